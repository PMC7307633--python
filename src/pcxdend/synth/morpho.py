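"""Stochastic dendritic-tree cohorts with known per-cell ground truth.

Trees are grown branch-by-branch in the slice plane: stems leave the soma,
then randomly chosen open tips bifurcate until the target branch count is
reached, so NB = stems + 2 * (number of bifurcations) and every branch count
decomposes exactly into stems + intermediates + tips.  Branch lengths are
log-normal (positive, right-skewed, matching the measured branch-length
densities qualitatively) with mean TDBL_target / E[NB], which makes the
cohort mean TDBL unbiased for its target.  Apical trees grow toward the
superficial layers and basal trees into layer 2/3, inside a straight-
boundary laminar geometry, so soma-depth normalization and termination-layer
classification are exercisable end to end.

The superficial-to-deep gradient of basal dendritic size is emulated by
scaling each cell's basal TDBL target with its depth in layer 2
(``basal_depth_slope``), and by giving layer 2a groups smaller basal targets
than layer 2b groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..layers import LayerGeometry, write_layer_geometry
from ..swc import APICAL, BASAL, SOMA, NeuronMorphology, SwcNode, write_swc

MIN_BRANCH_LENGTH_UM = 5.0
SEGMENTS_PER_BRANCH = 5

# straight-boundary laminar frame (µm), deeper_is "+y":
# L1a/L1b at y = -L1B_WIDTH, L1b/L2a at y = 0, L2/L3 at y = LAYER2_WIDTH
LAYER2_WIDTH = 120.0
L1B_WIDTH = 80.0
FRAME_HALF_EXTENT = 600.0


@dataclass(frozen=True)
class CohortGroupSpec:
    """Targets for one (cell_class, age_group) cohort cell group."""

    cell_class: str                       # "L2A" | "L2B"
    age_group: str = "p12-p14"
    apical_nb_mean: float = 25.0
    apical_tdbl: float = 1800.0
    basal_nb_mean: float = 12.0
    basal_tdbl: float = 800.0
    bl_cv: float = 0.5                    # log-normal coefficient of variation
    apical_stem_range: tuple[int, int] = (1, 3)
    basal_stem_range: tuple[int, int] = (2, 5)
    depth_range: tuple[float, float] = (0.0, 1.0)
    basal_depth_slope: float = 0.0        # relative TDBL change per unit depth

    def __post_init__(self) -> None:
        if min(self.apical_nb_mean, self.apical_tdbl,
               self.basal_nb_mean, self.basal_tdbl) <= 0:
            raise ValueError("targets must be positive")
        if not (0.0 <= self.depth_range[0] < self.depth_range[1] <= 1.0 + 1e-9):
            raise ValueError("depth_range must be within [0, 1]")
        for nb, tdbl, label in ((self.apical_nb_mean, self.apical_tdbl, "apical"),
                                (self.basal_nb_mean, self.basal_tdbl, "basal")):
            if tdbl < nb * MIN_BRANCH_LENGTH_UM:
                raise ValueError(
                    f"infeasible {label} targets: TDBL {tdbl} < "
                    f"NB {nb} x {MIN_BRANCH_LENGTH_UM} µm")


@dataclass(frozen=True)
class MorphCohortSpec:
    groups: tuple[CohortGroupSpec, ...]

    def __post_init__(self) -> None:
        by_age: dict[str, dict[str, float]] = {}
        for g in self.groups:
            by_age.setdefault(g.age_group, {})[g.cell_class] = g.basal_tdbl
        for age, classes in by_age.items():
            if {"L2A", "L2B"} <= classes.keys() and \
                    not classes["L2A"] < classes["L2B"]:
                raise ValueError(f"{age}: L2A basal targets must be below L2B")


def default_cohort_spec() -> MorphCohortSpec:
    """Critical-period (p12-p14) cohort: apical TDBL ~1800 µm with mean BL
    ~72 µm in both classes; basal trees smaller and shallower in layer 2a
    than layer 2b, with a positive within-group depth gradient."""
    return MorphCohortSpec(groups=(
        CohortGroupSpec("L2A", basal_nb_mean=7.0, basal_tdbl=420.0,
                        depth_range=(0.02, 1 / 3), basal_depth_slope=0.8),
        CohortGroupSpec("L2B", basal_nb_mean=14.0, basal_tdbl=900.0,
                        depth_range=(1 / 3, 0.98), basal_depth_slope=0.8),
    ))


def default_layer_geometry() -> LayerGeometry:
    xs = np.linspace(-FRAME_HALF_EXTENT, FRAME_HALF_EXTENT, 5)
    line = lambda y: np.column_stack([xs, np.full_like(xs, y)])
    return LayerGeometry(line(-L1B_WIDTH), line(0.0), line(LAYER2_WIDTH),
                         deeper_is="+y")


@dataclass
class MorphCohort:
    cells: list[NeuronMorphology]
    geometry: LayerGeometry
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for morph in self.cells:
            write_swc(morph, out_dir / f"{morph.metadata['cell_id']}.swc")
        write_layer_geometry(self.geometry, out_dir / "layers.csv")
        self.truth.to_csv(out_dir / "ground_truth.csv", index=False)


def gen_morphology_cohort(spec: MorphCohortSpec, n_cells: int,
                          seed: int = 0) -> MorphCohort:
    """Generate ``n_cells`` neurons per group, with per-cell ground truth.

    The truth table records the realized NB, stems, TDBL and mean BL of each
    compartment (recomputed from the final node coordinates, so they match a
    morphometry read-back up to float formatting), the depth-scaled targets,
    and the soma depth.
    """
    rng = np.random.default_rng(seed)
    geometry = default_layer_geometry()
    cells: list[NeuronMorphology] = []
    rows = []
    for g, group in enumerate(spec.groups):
        for c in range(n_cells):
            cell_id = f"{group.cell_class}_{group.age_group}_{c:03d}"
            depth = float(rng.uniform(*group.depth_range))
            morph, truth = _gen_cell(group, depth, rng)
            morph.metadata.update(cell_id=cell_id, age_group=group.age_group,
                                  cell_class=group.cell_class, depth_norm=depth)
            truth.update(cell_id=cell_id, age_group=group.age_group,
                         cell_class=group.cell_class, depth_norm=depth)
            cells.append(morph)
            rows.append(truth)
    return MorphCohort(cells, geometry, pd.DataFrame(rows))


def _gen_cell(group: CohortGroupSpec, depth: float,
              rng: np.random.Generator) -> tuple[NeuronMorphology, dict]:
    soma_xy = np.array([rng.uniform(-200.0, 200.0), depth * LAYER2_WIDTH])
    nodes = [SwcNode(1, SOMA, soma_xy[0], soma_xy[1], 0.0, 5.0, -1)]
    truth: dict = {}
    mid = 0.5 * (group.depth_range[0] + group.depth_range[1])
    basal_scale = max(0.1, 1.0 + group.basal_depth_slope * (depth - mid))
    plans = {
        "apical": (APICAL, group.apical_nb_mean, group.apical_tdbl,
                   group.apical_stem_range, -np.pi / 2),
        "basal": (BASAL, group.basal_nb_mean, group.basal_tdbl * basal_scale,
                  group.basal_stem_range, np.pi / 2),
    }
    for comp, (tcode, nb_mean, tdbl, stem_range, base_dir) in plans.items():
        n_stems = int(rng.integers(stem_range[0], stem_range[1] + 1))
        k_mean = max(0.0, (nb_mean - np.mean(stem_range)) / 2.0)
        k = int(rng.poisson(k_mean))
        nb = n_stems + 2 * k
        bl_mean = tdbl / nb_mean
        sigma2 = np.log(1.0 + group.bl_cv ** 2)
        mu = np.log(bl_mean) - sigma2 / 2.0
        lengths = np.maximum(MIN_BRANCH_LENGTH_UM,
                             rng.lognormal(mu, np.sqrt(sigma2), size=nb))
        stats = _grow_compartment(nodes, tcode, soma_xy, n_stems, k, lengths,
                                  base_dir, rng)
        truth.update({
            f"{comp}_nb": nb, f"{comp}_n_stems": n_stems,
            f"{comp}_tdbl": stats["tdbl"],
            f"{comp}_mean_bl": stats["tdbl"] / nb,
            f"{comp}_tdbl_target": tdbl, f"{comp}_nb_target": nb_mean,
        })
    return NeuronMorphology(nodes), truth


def _grow_compartment(nodes: list[SwcNode], tcode: int, soma_xy: np.ndarray,
                      n_stems: int, n_bifurcations: int, lengths: np.ndarray,
                      base_dir: float, rng: np.random.Generator) -> dict:
    """Grow stems then bifurcate random open tips; mutates ``nodes``."""
    open_tips: list[tuple[int, np.ndarray, float]] = []  # (node id, xy, heading)
    li = 0
    tdbl = 0.0
    for _ in range(n_stems):
        heading = base_dir + rng.uniform(-0.6, 0.6)
        tip, xy, tdbl_inc = _grow_branch(nodes, tcode, 1, soma_xy,
                                         heading, lengths[li], rng)
        open_tips.append((tip, xy, heading))
        li += 1
        tdbl += tdbl_inc
    for _ in range(n_bifurcations):
        j = int(rng.integers(len(open_tips)))
        parent_id, xy, heading = open_tips.pop(j)
        split = rng.uniform(0.3, 0.8)
        for sign in (-1.0, 1.0):
            child_heading = heading + sign * split + rng.uniform(-0.15, 0.15)
            tip, txy, tdbl_inc = _grow_branch(nodes, tcode, parent_id, xy,
                                              child_heading, lengths[li], rng)
            open_tips.append((tip, txy, child_heading))
            li += 1
            tdbl += tdbl_inc
    return {"tdbl": tdbl}


def _grow_branch(nodes: list[SwcNode], tcode: int, parent_id: int,
                 start_xy: np.ndarray, heading: float, length: float,
                 rng: np.random.Generator) -> tuple[int, np.ndarray, float]:
    seg_len = length / SEGMENTS_PER_BRANCH
    xy = start_xy.copy()
    pid = parent_id
    tdbl = 0.0
    for _ in range(SEGMENTS_PER_BRANCH):
        heading += rng.uniform(-0.12, 0.12)    # gentle meander, planar
        nxt = xy + seg_len * np.array([np.cos(heading), np.sin(heading)])
        nid = nodes[-1].id + 1
        nodes.append(SwcNode(nid, tcode, nxt[0], nxt[1], 0.0, 0.5, pid))
        tdbl += float(np.linalg.norm(nxt - xy))
        xy, pid = nxt, nid
    return pid, xy, tdbl
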