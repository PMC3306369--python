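import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import paleomacro as pm

from conftest import random_matrix


def _loop_dissimilarity(row_a, row_b):
    """Independent cell-loop oracle for one pair."""
    comp = diff = 0
    for a, b in zip(row_a, row_b):
        if a and b:
            comp += 1
            if not (a & b):
                diff += 1
    return (diff / comp) if comp else None


@pytest.fixture(scope="module")
def random_dissim():
    rng = np.random.default_rng(3)
    n = 8
    d = rng.random((n, n)) * 0.8
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return pm.DissimilarityMatrix([f"t{i}" for i in range(n)], d,
                                  np.full((n, n), 50))


class TestPairwiseDissimilarity:
    def test_identical_rows_have_zero_dissimilarity(self):
        m = random_matrix(0, n_taxa=2, n_chars=20)
        m.cells[1] = list(m.cells[0])
        d = pm.pairwise_dissimilarity(m)
        assert d.value("T0", "T1") == 0.0

    def test_shared_polymorphic_state_is_agreement(self):
        m = pm.CharacterMatrix(
            ["A", "B"],
            [[frozenset({0, 1}), frozenset({0})],
             [frozenset({1}), frozenset({2})]])
        d = pm.pairwise_dissimilarity(m)
        assert d.value("A", "B") == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_cell_loop_oracle(self, seed):
        m = random_matrix(seed, n_taxa=6, n_chars=40, missing=0.35)
        d = pm.pairwise_dissimilarity(m)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = _loop_dissimilarity(m.cells[i], m.cells[j])
                got = d.d[i, j]
                if expect is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect)

    def test_undefined_pair_flagged(self):
        m = pm.CharacterMatrix(
            ["cranial_only", "postcranial_only"],
            [[frozenset({0}), frozenset()],
             [frozenset(), frozenset({1})]])
        d = pm.pairwise_dissimilarity(m)
        assert d.undefined_pairs() == [("cranial_only", "postcranial_only")]


class TestDropUndefinedTaxa:
    def test_fully_comparable_matrix_unchanged(self):
        m = random_matrix(1, n_taxa=5, n_chars=20)
        d = pm.pairwise_dissimilarity(m)
        assert pm.drop_undefined_taxa(d).taxa == d.taxa

    def test_block_masked_taxon_removed(self):
        """A taxon with 100% postcranial missing data cannot be compared
        with postcranium-only taxa and must be deleted."""
        cfg = pm.SimConfig(seed=2, n_taxa=8, n_characters=40,
                           missing_fraction=0.0)
        tt, _ = pm.simulate_tree_with_ranges(cfg)
        mat = pm.simulate_matrix(
            tt, cfg, block_mask={"t01": (20, 40), "t02": (0, 20)})
        d = pm.pairwise_dissimilarity(mat)
        assert len(d.undefined_pairs()) >= 1
        cleaned = pm.drop_undefined_taxa(d)
        assert cleaned.undefined_pairs() == []
        assert len(cleaned.taxa) < len(d.taxa)


class TestPCoA:
    def test_three_equidistant_taxa(self):
        d = pm.DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, .5, .5], [.5, 0, .5], [.5, .5, 0]]),
            np.full((3, 3), 10))
        o = pm.pcoa(d)
        assert o.cailliez_constant == 0.0
        assert o.eigenvalues == pytest.approx([0.125, 0.125])
        # equilateral triangle: all pairwise score distances equal
        dist = pdist(o.scores)
        assert dist == pytest.approx([0.5] * 3)

    def test_euclidean_input_needs_no_correction(self):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 3))
        d = squareform(pdist(pts))
        dm = pm.DissimilarityMatrix([f"t{i}" for i in range(6)], d,
                                    np.full((6, 6), 10))
        o = pm.pcoa(dm)
        assert o.cailliez_constant == 0.0

    def test_scores_reconstruct_corrected_dissimilarities(self,
                                                          random_dissim):
        """Distance-reconstruction oracle: full-dimensional scores must
        reproduce the Cailliez-corrected dissimilarities to 1e-8."""
        o = pm.pcoa(random_dissim)
        assert o.cailliez_constant > 0
        rec = squareform(pdist(o.scores))
        n = len(random_dissim.taxa)
        corrected = random_dissim.d + o.cailliez_constant * (1 - np.eye(n))
        assert np.abs(rec - corrected).max() < 1e-8

    def test_axes_sorted_and_percentages_sum_to_100(self, random_dissim):
        o = pm.pcoa(random_dissim)
        assert (np.diff(o.eigenvalues) <= 1e-12).all()
        assert o.percent_per_axis.sum() == pytest.approx(100.0)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, .5], [.4, 0]])
        dm = pm.DissimilarityMatrix(["A", "B"], d, np.full((2, 2), 5))
        with pytest.raises(ValueError):
            pm.pcoa(dm)

    def test_undefined_pairs_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        dm = pm.DissimilarityMatrix(["A", "B"], d, np.zeros((2, 2), int))
        with pytest.raises(ValueError):
            pm.pcoa(dm)


class TestAxisPercentages:
    def test_all_axes_is_100(self, random_dissim):
        o = pm.pcoa(random_dissim)
        assert pm.axis_percentages(o, o.n_axes) == pytest.approx(100.0)

    def test_zero_axes_is_zero(self, random_dissim):
        assert pm.axis_percentages(pm.pcoa(random_dissim), 0) == 0.0


class TestDisparityMetrics:
    def test_two_taxon_mpd_is_their_dissimilarity(self, random_dissim):
        got = pm.mean_pairwise_dissimilarity(random_dissim, ["t0", "t3"])
        assert got == pytest.approx(random_dissim.value("t0", "t3"))

    def test_mpd_matches_flat_average_oracle(self, random_dissim):
        taxa = ["t0", "t2", "t4", "t5"]
        vals = [random_dissim.value(a, b)
                for i, a in enumerate(taxa) for b in taxa[i + 1:]]
        assert pm.mean_pairwise_dissimilarity(random_dissim, taxa) == \
            pytest.approx(np.mean(vals))

    def test_singleton_mpd_absent(self, random_dissim):
        assert pm.mean_pairwise_dissimilarity(random_dissim, ["t0"]) is None

    def test_sov_of_duplicated_point_is_zero(self):
        o = pm.Ordination(["a", "b"], np.ones((2, 3)), np.ones(3), 0.0)
        assert pm.sum_of_variances(o) == pytest.approx(0.0)

    def test_sov_translation_invariance(self, random_dissim):
        o = pm.pcoa(random_dissim)
        shifted = pm.Ordination(o.taxa, o.scores + 7.5, o.eigenvalues,
                                o.cailliez_constant)
        assert pm.sum_of_variances(shifted) == \
            pytest.approx(pm.sum_of_variances(o))

    def test_sov_distance_identity(self, random_dissim):
        """On the full set, SoV = ½ · mean squared corrected distance
        · n/(n−1)."""
        o = pm.pcoa(random_dissim)
        n = len(o.taxa)
        sq = pdist(o.scores) ** 2
        mean_sq = sq.sum() * 2 / (n * n)   # mean over ordered pairs
        expect = 0.5 * mean_sq * n / (n - 1)
        assert pm.sum_of_variances(o) == pytest.approx(expect)


class TestRarefaction:
    def test_full_pool_sample_gives_degenerate_ci(self, random_dissim):
        lo, hi, point = pm.rarefaction_ci(
            "mpd", random_dissim, random_dissim.taxa,
            len(random_dissim.taxa), n_resamples=100, seed=1)
        assert lo == pytest.approx(point)
        assert hi == pytest.approx(point)

    def test_fixed_seed_bit_reproducible(self, random_dissim):
        a = pm.rarefaction_ci("mpd", random_dissim, random_dissim.taxa, 4,
                              n_resamples=200, seed=9)
        b = pm.rarefaction_ci("mpd", random_dissim, random_dissim.taxa, 4,
                              n_resamples=200, seed=9)
        assert a == b

    def test_ci_width_shrinks_with_sample_size(self, random_dissim):
        widths = []
        for size in (3, 5, 8):
            lo, hi, _ = pm.rarefaction_ci("mpd", random_dissim,
                                          random_dissim.taxa, size,
                                          n_resamples=500, seed=4)
            widths.append(hi - lo)
        assert widths[0] > widths[-1]
        assert widths[-1] == pytest.approx(0.0, abs=1e-12)  # full pool

    def test_tiny_sample_rejected(self, random_dissim):
        with pytest.raises(ValueError):
            pm.rarefaction_ci("mpd", random_dissim, random_dissim.taxa, 1)


def test_monotonic_divergence_yields_monotonic_disparity():
    """A later assemblage generated with more character-state divergence
    must show strictly larger MPD and SoV than an earlier one."""
    rng = np.random.default_rng(8)
    taxa, cells, assignments = [], [], {}
    base = [frozenset({0})] * 60
    for bin_label, flip_p in (("early", 0.05), ("late", 0.35)):
        for i in range(6):
            name = f"{bin_label}_{i}"
            taxa.append(name)
            assignments[name] = bin_label
            cells.append([
                frozenset({int(rng.integers(1, 3))})
                if rng.random() < flip_p else c
                for c in base
            ])
    m = pm.CharacterMatrix(taxa, cells)
    d = pm.pairwise_dissimilarity(m)
    o = pm.pcoa(d)
    early = [t for t in taxa if t.startswith("early")]
    late = [t for t in taxa if t.startswith("late")]
    assert pm.mean_pairwise_dissimilarity(d, late) > \
        pm.mean_pairwise_dissimilarity(d, early)
    assert pm.sum_of_variances(o, late) > pm.sum_of_variances(o, early)
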