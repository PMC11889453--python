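import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltnn import CellMatrix, ValidationError
from ltnn.io import make_mito_mask
from ltnn.preprocess import (
    distribution_features,
    ks_similarity,
    ks_similarity_matrix,
    nhvg_set,
    normalize_total,
    qc_filter,
    select_hvgs,
    variability_scores,
)


def make_matrix(counts, mito=None, gene_ids=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(g)]
    return CellMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=gene_ids,
        mito_mask=mito if mito is not None else np.zeros(g, dtype=bool),
    )


class TestQCFilter:
    def test_count_threshold_keeps_boundary(self):
        m = make_matrix(np.diag([999, 1000, 5000]))
        out = qc_filter(m)
        assert list(out.cell_ids) == ["c1", "c2"]

    def test_mito_boundary_strictly_above(self):
        counts = np.array([[790, 210], [800, 200]]) * 10  # fractions 0.21, 0.20
        m = make_matrix(counts, mito=np.array([False, True]))
        out = qc_filter(m)
        assert list(out.cell_ids) == ["c1"]

    def test_no_mito_genes_only_count_rule(self):
        m = make_matrix(np.array([[2000, 0], [500, 100]]))
        out = qc_filter(m)
        assert list(out.cell_ids) == ["c0"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 100, (20, 50)))
        once = qc_filter(m, min_counts=2000)
        twice = qc_filter(once, min_counts=2000)
        np.testing.assert_array_equal(once.counts_dense(), twice.counts_dense())

    def test_all_removed_is_error(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValidationError, match="min_counts"):
            qc_filter(m)


class TestNormalize:
    def test_plain_fraction(self):
        m = normalize_total(make_matrix([[2, 3, 5]]))
        np.testing.assert_allclose(m.normalized_dense()[0], [0.2, 0.3, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = normalize_total(make_matrix(rng.integers(1, 50, (10, 8))))
        np.testing.assert_allclose(m.normalized_dense().sum(axis=1), 1.0)

    def test_target_sum_and_log1p_closed_form(self):
        m = normalize_total(make_matrix([[1, 0]]), target_sum=10, log1p=True)
        np.testing.assert_allclose(m.normalized_dense()[0], [np.log(11), 0.0])

    def test_zero_total_cell_named(self):
        with pytest.raises(ValidationError, match="c1"):
            normalize_total(make_matrix([[1, 1], [0, 0]]))

    def test_raw_counts_retained(self):
        m = normalize_total(make_matrix([[2, 3, 5]]), log1p=True)
        assert m.counts_dense().tolist() == [[2, 3, 5]]


def brute_force_scores(counts, trend_degree=2):
    """Independent clipped-standardized-variance computation."""
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    ok = (mean > 0) & (var > 0)
    coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), trend_degree)
    scores = np.zeros(g)
    for j in range(g):
        if not ok[j]:
            continue
        sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[j])))
        z = np.minimum((counts[:, j] - mean[j]) / sd, np.sqrt(n))
        scores[j] = z.var(ddof=1)
    return scores


class TestHVGSelection:
    def test_constant_gene_scores_zero_and_ranks_last(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, (50, 20))
        counts[:, 7] = 5
        hvg = select_hvgs(make_matrix(counts), hvg_count=19)
        assert hvg.scores[7] == 0.0
        assert hvg.ranked_gene_ids[-1] == "g007"
        assert not hvg.selected_mask[7]

    def test_shifted_genes_occupy_top_ranks(self):
        # 180 Poisson background genes span means 1..200 and anchor the
        # mean-variance trend; 20 genes with a 10x mean shift in half the
        # cells are then far above their trend-predicted variance
        rng = np.random.default_rng(2)
        bg = rng.poisson(np.logspace(0, np.log10(200), 180), size=(100, 180))
        sig = rng.poisson(10.0, size=(100, 20))
        sig[:50] = rng.poisson(100.0, size=(50, 20))
        counts = np.hstack([sig, bg])
        m = make_matrix(counts)
        hvg = select_hvgs(m, hvg_count=20)
        top = set(np.flatnonzero(hvg.selected_mask))
        assert top == set(range(20))
        np.testing.assert_allclose(
            hvg.scores, brute_force_scores(counts), rtol=1e-10
        )

    def test_hvg_count_clamped_to_gene_total(self):
        rng = np.random.default_rng(3)
        hvg = select_hvgs(make_matrix(rng.integers(0, 20, (30, 50))), hvg_count=10_000)
        assert hvg.n_selected == 50

    def test_invalid_count_rejected(self):
        with pytest.raises(ValidationError):
            select_hvgs(make_matrix(np.ones((5, 5))), hvg_count=0)


class TestNHVG:
    def test_recurrence_boundary_inclusive(self):
        counts = np.zeros((100, 3))
        counts[:, 0] = np.random.default_rng(0).integers(1, 60, 100)  # HVG bait
        counts[:9, 1] = 1    # 9% of cells
        counts[:10, 2] = 1   # 10% of cells
        m = make_matrix(counts)
        hvg = select_hvgs(m, hvg_count=1)
        genes = set(nhvg_set(hvg, m, recurrence_frac=0.1))
        assert "g002" in genes and "g001" not in genes

    def test_disjoint_from_selected_and_excludes_silent(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, (40, 30))
        counts[:, 5] = 0
        m = make_matrix(counts)
        hvg = select_hvgs(m, hvg_count=10)
        genes = set(nhvg_set(hvg, m))
        assert not genes & set(hvg.gene_ids[hvg.selected_mask])
        assert "g005" not in genes


class TestDistributionFeatures:
    def _features(self, counts, hvg_count=4):
        m = normalize_total(make_matrix(counts))
        hvg = select_hvgs(m, hvg_count=hvg_count)
        return distribution_features(m, hvg), hvg

    def test_constant_cell_degenerate_stats(self):
        m = normalize_total(make_matrix(np.ones((3, 4))))
        hvg = select_hvgs(m, hvg_count=4)
        f = distribution_features(m, hvg)
        np.testing.assert_allclose(f.std, 0.0)
        np.testing.assert_allclose(f.max, 0.25)
        np.testing.assert_allclose(f.median, 0.25)

    def test_max_dominates_mean_and_median(self):
        rng = np.random.default_rng(4)
        f, _ = self._features(rng.integers(1, 50, (20, 10)), hvg_count=6)
        assert (f.max >= f.mean).all() and (f.max >= f.median).all()

    def test_even_length_median_convention(self):
        assert np.median([0, 1, 2, 3]) == 1.5  # convention used throughout


def brute_force_ks(a, b):
    points = np.concatenate([a, b])
    best = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestKSSimilarity:
    def test_identical_samples_zero(self):
        a = np.array([0.1, 0.5, 0.9])
        assert ks_similarity(a, a.copy()) == 0.0

    def test_disjoint_supports_one(self):
        rng = np.random.default_rng(0)
        assert ks_similarity(rng.uniform(0, 1, 30), rng.uniform(2, 3, 40)) == 1.0

    def test_matches_exhaustive_ecdf_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=50)
            b = rng.normal(0.3, 1.2, size=50)
            assert abs(ks_similarity(a, b) - brute_force_ks(a, b)) < 1e-12

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.lists(st.floats(-5, 5), min_size=1, max_size=30),
        b=st.lists(st.floats(-5, 5), min_size=1, max_size=30),
    )
    def test_symmetric_and_bounded(self, a, b):
        d = ks_similarity(a, b)
        assert 0.0 <= d <= 1.0
        assert d == ks_similarity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ks_similarity([], [1.0])

    def test_matrix_variant_symmetric_zero_diag(self):
        rng = np.random.default_rng(6)
        feats = []
        for i in range(3):
            counts = rng.integers(1, 40, (30, 20))
            m = normalize_total(make_matrix(counts))
            feats.append(distribution_features(m, select_hvgs(m, hvg_count=10)))
        k = ks_similarity_matrix(feats)
        np.testing.assert_array_equal(k, k.T)
        np.testing.assert_array_equal(np.diag(k), 0.0)


def test_same_generator_features_closer_than_different_dispersion():
    """Std-feature distributions are more alike across seeds of one
    generator than across generators with very different dispersion."""
    from ltnn import simulate_trajectory

    def std_features(dispersion, seed):
        m, _ = simulate_trajectory(
            n_cells=150, n_genes=150, n_branches=1, dispersion=dispersion,
            seed=seed,
        )
        m = normalize_total(m, log1p=True)
        return distribution_features(m, select_hvgs(m, hvg_count=100))

    same = [std_features(10.0, s) for s in (0, 1, 2)]
    other = std_features(0.3, 0)
    within = np.mean(
        [ks_similarity(a.std, b.std) for a, b in [(same[0], same[1]),
                                                  (same[0], same[2]),
                                                  (same[1], same[2])]]
    )
    across = np.mean([ks_similarity(s.std, other.std) for s in same])
    assert within < across
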