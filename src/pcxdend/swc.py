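"""Reading and writing neuronal reconstructions in the 7-column SWC format.

SWC is the de-facto plain-text interchange format for single-neuron
reconstructions: one node per line with ``id type x y z radius parent``,
``#`` comments, and ``parent = -1`` marking the root.  Type codes follow the
usual convention (1 = soma, 3 = basal dendrite, 4 = apical dendrite); other
codes are preserved but ignored by the morphometry layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

SOMA = 1
BASAL = 3
APICAL = 4

DENDRITE_TYPES = (BASAL, APICAL)


class SwcParseError(ValueError):
    """Structural problem in an SWC file; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SwcNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronMorphology:
    """A rooted tree of 3-D points partitioned into soma/apical/basal.

    ``children`` maps node id -> list of child ids in file order.  The soma
    centroid is the unweighted mean of all soma-node coordinates (falling
    back to the root node if no node carries the soma type code).
    """

    nodes: list[SwcNode]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {n.id: n for n in self.nodes}
        self.children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        roots = []
        for n in self.nodes:
            if n.parent_id == -1:
                roots.append(n.id)
            else:
                self.children[n.parent_id].append(n.id)
        if len(roots) != 1:
            raise SwcParseError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0]

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    @property
    def soma_nodes(self) -> list[SwcNode]:
        soma = [n for n in self.nodes if n.type_code == SOMA]
        return soma if soma else [self._by_id[self.root_id]]

    @property
    def soma_centroid(self) -> np.ndarray:
        return np.mean([n.xyz for n in self.soma_nodes], axis=0)

    def is_soma(self, node_id: int) -> bool:
        return self._by_id[node_id].type_code == SOMA or node_id == self.root_id

    def dendritic_nodes(self, compartment: str | None = None) -> list[SwcNode]:
        if compartment is None:
            codes = DENDRITE_TYPES
        else:
            codes = {"apical": (APICAL,), "basal": (BASAL,)}[compartment]
        return [n for n in self.nodes if n.type_code in codes]


def read_swc(path: str | Path) -> NeuronMorphology:
    """Parse an SWC file into a validated :class:`NeuronMorphology`.

    Raises :class:`SwcParseError` naming the offending line for duplicate
    ids, dangling parents (a parent id that has not appeared earlier in file
    order), malformed columns, or a missing/duplicated root.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    seen: set[int] = set()
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"expected 7 columns, got {len(parts)}", line_no)
            try:
                nid = int(parts[0])
                tcode = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"malformed value ({exc})", line_no) from exc
            if nid in seen:
                raise SwcParseError(f"duplicate node id {nid}", line_no)
            if parent != -1 and parent not in seen:
                # also catches self-reference and any forward/cyclic reference
                raise SwcParseError(
                    f"parent id {parent} does not precede node {nid}", line_no)
            seen.add(nid)
            nodes.append(SwcNode(nid, tcode, x, y, z, radius, parent))
    if not nodes:
        raise SwcParseError("no nodes in file")
    return NeuronMorphology(nodes)


def write_swc(morph: NeuronMorphology | Iterable[SwcNode], path: str | Path,
              header: str | None = None) -> None:
    nodes = morph.nodes if isinstance(morph, NeuronMorphology) else list(morph)
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for n in nodes:
            fh.write(f"{n.id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                     f"{n.radius:.6g} {n.parent_id}\n")
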