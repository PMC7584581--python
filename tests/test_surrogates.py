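"""Constrained weight permutation: cells, conservation laws, adjustment."""

import numpy as np
import pytest

from conftest import toy_connectome, two_cliques
from segint.connectome import weighted_rich_club
from segint.surrogates import (BinSelectionError, CellPartition, RsnPairError,
                               adjust_strength_sequence, assign_length_bins,
                               build_cells, detect_structural_communities,
                               make_rsn_pair, make_surrogate,
                               permute_within_cells, richclub_categories,
                               select_length_bins)
from segint.synthetic import generate_connectome, generate_geometry


@pytest.fixture(scope="module")
def frozen(desk_connectome):
    """Community partition and bin spec frozen from the parent."""
    part = detect_structural_communities(desk_connectome, seed=11)
    bins = select_length_bins(desk_connectome, n_bins_override=30)
    return part, bins


class TestBinSelection:
    def test_many_uniform_edges_accept_first_candidate(self):
        rng = np.random.default_rng(0)
        n = 101
        W = np.ones((n, n)) - np.eye(n)
        L = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        L[iu] = rng.uniform(10, 150, len(iu[0]))
        L += L.T
        spec = select_length_bins(toy_connectome(W, L))
        assert spec.n_bins == 100
        # direct count: ~50 edges expected per bin, far above the sparse cut
        assert spec.edges_per_bin.min() > 3

    def test_identical_lengths_fail_scan_deterministically(self):
        """All edges share one bin, so empty bins violate both criteria at
        every candidate count and the scan fails explicitly."""
        W = np.zeros((13, 13))
        for i in range(12):
            W[i, i + 1] = W[i + 1, i] = 1.0
        L = np.where(W > 0, 25.0, 0.0)
        with pytest.raises(BinSelectionError, match="criteria"):
            select_length_bins(toy_connectome(W, L))

    def test_override_gives_exact_bin_count(self, desk_connectome):
        spec = select_length_bins(desk_connectome, n_bins_override=30)
        assert spec.n_bins == 30
        assert len(spec.boundaries) == 31
        assert np.all(np.diff(spec.boundaries) > 0)

    def test_accepted_scan_meets_both_criteria(self, default_connectome):
        spec = select_length_bins(default_connectome)
        assert spec.sparse_bin_percentage <= 10.0
        assert spec.edges_per_bin.min() > 1

    def test_half_open_bin_assignment(self):
        lengths = np.array([0.0, 1.0, 2.0, 4.0])
        idx, bounds = assign_length_bins(lengths, 4)
        assert np.array_equal(idx, [0, 1, 2, 3])   # max falls in closed last bin
        assert np.allclose(bounds, [0, 1, 2, 3, 4])


class TestCommunityDetection:
    def test_two_cliques_recovered(self):
        W, planted = two_cliques()
        labels = detect_structural_communities(toy_connectome(W), seed=0)
        assert _same_partition(labels, planted)

    def test_uniform_complete_graph_has_no_modular_structure(self):
        from segint.netmeasures import qstar
        W = np.ones((6, 6)) - np.eye(6)
        c = toy_connectome(W)
        labels = detect_structural_communities(c, seed=0)
        assert qstar(W, labels) <= qstar(W, np.zeros(6, int)) + 1e-12

    def test_planted_partition_recovery_at_strong_multipliers(self):
        nodes = generate_geometry(60, seed=9)
        c = generate_connectome(nodes, target_density=0.3, decay_scale=np.inf,
                                n_communities=4, community_multiplier=12.0,
                                hub_multiplier=1.0, homotopic_multiplier=1.0,
                                noise_sigma=0.2, seed=9)
        planted = c.nodes["community"].to_numpy()
        labels = detect_structural_communities(c, seed=4)
        assert _same_partition(labels, planted)


class TestRichClubCategories:
    def test_star_leaves_in_category_one(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        assert np.array_equal(richclub_categories(toy_connectome(W)),
                              np.ones(4, int))

    def test_triangle_category_two(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert np.array_equal(richclub_categories(toy_connectome(W)),
                              np.full(3, 2))

    def test_within_category_permutation_preserves_rich_club_curve(
            self, desk_connectome):
        c = desk_connectome
        cats = richclub_categories(c)
        cells = CellPartition(
            [np.flatnonzero(cats == v) for v in np.unique(cats)],
            n_edges=len(cats), constraint_tags=("richclub",))
        surr = permute_within_cells(c, cells, seed=21).connectome
        before = weighted_rich_club(c)["phi_w"].to_numpy()
        after = weighted_rich_club(surr)["phi_w"].to_numpy()
        assert np.allclose(before, after, rtol=0, atol=1e-12, equal_nan=True)


class TestCells:
    def test_unconstrained_family_is_fully_permutable(self, desk_connectome):
        cells = build_cells(desk_connectome, "R")
        assert cells.permutable_fraction == 1.0

    def test_refinement_never_increases_permutable_fraction(
            self, desk_connectome, frozen):
        part, bins = frozen
        frac = {fam: build_cells(desk_connectome, fam, bins=bins,
                                 partition=part).permutable_fraction
                for fam in ("R", "G", "T", "GT")}
        assert frac["R"] >= frac["G"] >= frac["GT"]
        assert frac["R"] >= frac["T"] >= frac["GT"]

    def test_all_singleton_cells_nothing_permutable(self):
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        cells = CellPartition([np.array([0]), np.array([1]), np.array([2])],
                              n_edges=3)
        assert cells.permutable_fraction == 0.0

    def test_mismatched_partition_rejected(self, desk_connectome, frozen):
        _, bins = frozen
        with pytest.raises(ValueError, match="partition"):
            build_cells(desk_connectome, "T", bins=bins,
                        partition=np.zeros(3, int))


class TestPermutation:
    def test_single_edge_cell_unchanged(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        W[1, 2] = W[2, 1] = 3.0
        c = toy_connectome(W)
        cells = CellPartition([np.array([0]), np.array([1])], n_edges=2)
        out = permute_within_cells(c, cells, seed=0)
        assert np.array_equal(out.connectome.W, W)

    def test_conservation_laws(self, desk_connectome, frozen):
        """Multiset, support, lengths, per-cell multisets conserved exactly."""
        part, bins = frozen
        c = desk_connectome
        for fam in ("R", "G", "T", "GT"):
            cells = build_cells(c, fam, bins=bins, partition=part)
            out = permute_within_cells(c, cells, seed=5).connectome
            i, j = c.edge_index()
            assert np.array_equal(np.sort(out.W[i, j]), np.sort(c.W[i, j]))
            assert np.array_equal(out.W > 0, c.W > 0)
            assert np.array_equal(out.L, c.L)
            for cell in cells.cells:
                assert np.array_equal(np.sort(out.W[i, j][cell]),
                                      np.sort(c.W[i, j][cell]))

    def test_geometry_family_preserves_per_bin_means_exactly(
            self, desk_connectome, frozen):
        part, bins = frozen
        c = desk_connectome
        cells = build_cells(c, "G", bins=bins)
        out = permute_within_cells(c, cells, seed=9).connectome
        i, j = c.edge_index()
        idx, _ = assign_length_bins(c.edge_lengths(), bins.n_bins)
        for b in np.unique(idx):
            assert np.isclose(out.W[i, j][idx == b].mean(),
                              c.W[i, j][idx == b].mean(), rtol=0, atol=1e-12)

    def test_gt_family_preserves_block_sums_and_rich_club(
            self, desk_connectome, frozen):
        part, bins = frozen
        c = desk_connectome
        cells = build_cells(c, "GT", bins=bins, partition=part)
        out = permute_within_cells(c, cells, seed=13).connectome
        i, j = c.edge_index()
        block = np.where(part[i] == part[j], part[i], -1)
        for b in np.unique(block):
            assert np.isclose(out.W[i, j][block == b].sum(),
                              c.W[i, j][block == b].sum(), rtol=0, atol=1e-9)
        assert np.allclose(weighted_rich_club(c)["phi_w"],
                           weighted_rich_club(out)["phi_w"],
                           rtol=0, atol=1e-12, equal_nan=True)

    def test_seed_determinism_and_variation(self, desk_connectome):
        cells = build_cells(desk_connectome, "R")
        a = permute_within_cells(desk_connectome, cells, seed=3).connectome.W
        b = permute_within_cells(desk_connectome, cells, seed=3).connectome.W
        c2 = permute_within_cells(desk_connectome, cells, seed=4).connectome.W
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c2)


class TestStrengthAdjustment:
    def test_identity_permutation_is_fixed_point(self, desk_connectome):
        c = desk_connectome
        cells = CellPartition([np.array([e]) for e in
                               range(len(c.edge_weights()))],
                              n_edges=len(c.edge_weights()))
        sample = permute_within_cells(c, cells, seed=0)
        out = adjust_strength_sequence(sample, c.strengths())
        assert np.allclose(out.connectome.W, c.W, rtol=1e-3)
        assert out.strength_error < 1e-3

    def test_strength_sequence_restored(self, desk_connectome, frozen):
        part, bins = frozen
        c = desk_connectome
        for fam in ("R", "G", "GT"):
            cells = build_cells(c, fam, bins=bins, partition=part)
            out = make_surrogate(c, cells, seed=31, family=fam)
            corr = np.corrcoef(c.strengths(),
                               out.connectome.strengths())[0, 1]
            assert corr > 0.999
            assert out.strength_error < 1e-3

    def test_adjustment_is_a_diagonal_rescaling(self, desk_connectome):
        """The converged correction factors as w'_ij = w_ij f_i f_j."""
        c = desk_connectome
        cells = build_cells(c, "R")
        permuted = permute_within_cells(c, cells, seed=8)
        adjusted = adjust_strength_sequence(permuted, c.strengths())
        i, j = c.edge_index()
        log_ratio = np.log(adjusted.connectome.W[i, j]
                           / permuted.connectome.W[i, j])
        design = np.zeros((len(i), c.n_nodes))
        design[np.arange(len(i)), i] = 1.0
        design[np.arange(len(i)), j] = 1.0
        fitted = design @ np.linalg.lstsq(design, log_ratio, rcond=None)[0]
        assert np.allclose(fitted, log_ratio, atol=1e-8)

    def test_geometry_profile_better_preserved_by_g_than_r(
            self, desk_connectome, frozen):
        """After adjustment, G retains the parent weight-length profile far
        better than R (the geometric constraint's purpose)."""
        part, bins = frozen
        c = desk_connectome
        i, j = c.edge_index()
        idx, _ = assign_length_bins(c.edge_lengths(), bins.n_bins)
        ub = np.unique(idx)
        parent_prof = np.log([c.W[i, j][idx == b].mean() for b in ub])

        def profile_corr(fam):
            cells = build_cells(c, fam, bins=bins, partition=part)
            out = make_surrogate(c, cells, seed=17, family=fam).connectome
            prof = np.log([out.W[i, j][idx == b].mean() for b in ub])
            return np.corrcoef(parent_prof, prof)[0, 1]

        corr_g, corr_r = profile_corr("G"), profile_corr("R")
        assert corr_g > 0.6
        assert corr_g > corr_r + 0.2


class TestRsnPairs:
    def test_main_control_counts_equalized(self, desk_connectome, frozen):
        part, bins = frozen
        gt = build_cells(desk_connectome, "GT", bins=bins, partition=part)
        main, control = make_rsn_pair(desk_connectome, gt, "VIS", seed=2)
        assert main.permutable_edges == control.permutable_edges

    def test_rsn_covering_all_nodes_fails(self, frozen):
        part, bins = frozen
        nodes = generate_geometry(57, seed=1)
        nodes = nodes.assign(rsn="VIS")
        from segint.synthetic import generate_connectome
        c = generate_connectome(nodes, seed=1)
        gt = build_cells(c, "R")
        with pytest.raises(RsnPairError, match="control"):
            make_rsn_pair(c, gt, "VIS", seed=0)

    def test_unknown_rsn_fails(self, desk_connectome):
        gt = build_cells(desk_connectome, "R")
        with pytest.raises(RsnPairError, match="not present"):
            make_rsn_pair(desk_connectome, gt, "XXX", seed=0)

    def test_main_pools_of_disjoint_rsns_share_cross_edges(
            self, desk_connectome, frozen):
        part, bins = frozen
        c = desk_connectome
        gt = build_cells(c, "GT", bins=bins, partition=part)
        main_a, _ = make_rsn_pair(c, gt, "VIS", seed=0)
        main_b, _ = make_rsn_pair(c, gt, "DMN", seed=0)
        labels = c.nodes["rsn"].to_numpy()
        i, j = c.edge_index()

        def permutable_set(cp):
            big = [cc for cc in cp.cells if len(cc) >= 2]
            return set(np.concatenate(big)) if big else set()

        both = permutable_set(main_a) & permutable_set(main_b)
        for e in both:
            ends = {labels[i[e]], labels[j[e]]}
            assert ends == {"VIS", "DMN"}


def _same_partition(a, b) -> bool:
    """Partitions equal up to label renaming."""
    a, b = np.asarray(a), np.asarray(b)
    return (len({(x, y) for x, y in zip(a, b)})
            == len(set(a)) == len(set(b)))
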