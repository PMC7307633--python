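import numpy as np
import pytest

from pcxdend.morphology import (cohort_table, decompose_branches,
                                density_profile, morphometry_summary)
from pcxdend.swc import (APICAL, BASAL, SOMA, NeuronMorphology, SwcNode,
                         read_swc)
from conftest import random_tree


def brute_force_tdbl(m):
    """Independent oracle: sum of Euclidean parent-child edge lengths over
    all dendritic nodes."""
    total = 0.0
    for n in m.nodes:
        if n.type_code in (APICAL, BASAL):
            total += float(np.linalg.norm(n.xyz - m.node(n.parent_id).xyz))
    return total


class TestToyTree:
    def test_branch_decomposition_exact(self, toy_swc_path):
        branches = decompose_branches(read_swc(toy_swc_path))
        assert sorted(b.kind for b in branches) == ["stem", "tip", "tip"]
        assert [pytest.approx(b.length) for b in branches] == [50, 50, 50]

    def test_summary_scalars_exact(self, toy_swc_path):
        s = morphometry_summary(read_swc(toy_swc_path)).apical
        assert (s.nb, s.n_stems, s.n_tips, s.n_intermediate) == (3, 1, 2, 0)
        assert s.tdbl == pytest.approx(150.0)
        assert s.mean_bl == pytest.approx(50.0)

    def test_empty_basal_compartment_zeroed(self, toy_swc_path):
        s = morphometry_summary(read_swc(toy_swc_path)).basal
        assert (s.nb, s.tdbl, s.mean_bl) == (0, 0.0, 0.0)
        assert s.density_profile is None


class TestPartitionInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_tdbl_equals_edge_sum_oracle(self, seed):
        m = random_tree(np.random.default_rng(seed))
        s = morphometry_summary(m)
        assert s.apical.tdbl + s.basal.tdbl == pytest.approx(
            brute_force_tdbl(m), rel=1e-12)

    def test_every_dendritic_edge_in_exactly_one_branch(self):
        m = random_tree(np.random.default_rng(3))
        edge_count: dict[int, int] = {}
        for b in decompose_branches(m):
            for nid in b.node_path[1:]:     # edge (parent(nid), nid)
                edge_count[nid] = edge_count.get(nid, 0) + 1
        dendritic = {n.id for n in m.nodes if n.type_code in (APICAL, BASAL)}
        assert set(edge_count) == dendritic
        assert set(edge_count.values()) == {1}

    def test_nb_identity_stems_plus_intermediates_plus_tips(self):
        m = random_tree(np.random.default_rng(7))
        s = morphometry_summary(m)
        for comp in (s.apical, s.basal):
            assert comp.nb == comp.n_stems + comp.n_tips + comp.n_intermediate

    def test_rigid_motion_leaves_morphometry_unchanged(self):
        rng = np.random.default_rng(11)
        m = random_tree(rng)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([13.0, -40.0, 7.0])
        moved = NeuronMorphology([
            SwcNode(n.id, n.type_code, *(rot @ n.xyz + shift), n.radius,
                    n.parent_id) for n in m.nodes])
        a, b = morphometry_summary(m), morphometry_summary(moved)
        for comp in ("apical", "basal"):
            ca, cb = getattr(a, comp), getattr(b, comp)
            assert ca.nb == cb.nb and ca.n_tips == cb.n_tips
            assert ca.tdbl == pytest.approx(cb.tdbl, rel=1e-9)
            assert np.allclose(np.sort(ca.branch_lengths),
                               np.sort(cb.branch_lengths))

    def test_inserting_degree2_node_changes_nothing(self, toy_swc_path):
        m = read_swc(toy_swc_path)
        # split the edge 2->3 at its midpoint with a new node id 8
        nodes = []
        for n in m.nodes:
            if n.id == 3:
                nodes.append(SwcNode(8, APICAL, 0, 37.5, 0, 1, 2))
                n = SwcNode(3, APICAL, n.x, n.y, n.z, n.radius, 8)
            nodes.append(n)
        s0, s1 = morphometry_summary(m), morphometry_summary(NeuronMorphology(nodes))
        assert s0.apical.nb == s1.apical.nb
        assert s0.apical.tdbl == pytest.approx(s1.apical.tdbl)

    def test_dendritic_root_rejected(self):
        m = NeuronMorphology([SwcNode(1, APICAL, 0, 0, 0, 1, -1),
                              SwcNode(2, APICAL, 5, 0, 0, 1, 1)])
        with pytest.raises(ValueError, match="root"):
            decompose_branches(m)


class TestDensityProfile:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        for values in (rng.uniform(10, 200, 50), [42.0], [30.0, 30.0]):
            grid, dens = density_profile(values)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-9)

    def test_kde_matches_fine_histogram(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(4.0, 25.0, size=200)
        grid, dens = density_profile(vals)
        hist, edges = np.histogram(vals, bins=30, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        kde_at_centers = np.interp(centers, grid, dens)
        assert np.mean(np.abs(kde_at_centers - hist)) < 0.2 * hist.max()


class TestCohortTable:
    def _cells(self, depths, basal_lengths):
        cells = []
        for d, L in zip(depths, basal_lengths):
            m = NeuronMorphology([
                SwcNode(1, SOMA, 0, 0, 0, 5, -1),
                SwcNode(2, BASAL, 0, L, 0, 1, 1),
                SwcNode(3, APICAL, 0, -30, 0, 1, 1)])
            m.metadata.update(age_group="p6-p8", cell_class=None, depth_norm=d)
            cells.append((m, morphometry_summary(m)))
        return cells

    def test_perfect_monotone_gives_rank_correlation_one(self):
        table, assoc = cohort_table(self._cells([0.1, 0.4, 0.6, 0.9],
                                                [10, 20, 40, 80]))
        assert len(table) == 4
        assert assoc.loc[0, "spearman_r"] == pytest.approx(1.0)

    def test_fewer_than_three_cells_missing_association(self):
        table, assoc = cohort_table(self._cells([0.2, 0.8], [10, 50]))
        assert len(table) == 2
        assert np.isnan(assoc.loc[0, "spearman_r"])

    def test_constant_vector_reports_missing(self):
        _, assoc = cohort_table(self._cells([0.2, 0.5, 0.8], [30, 30, 30]))
        assert np.isnan(assoc.loc[0, "spearman_r"])
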