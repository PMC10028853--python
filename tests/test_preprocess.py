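import numpy as np
import pytest

from regdiff.io_formats import GeneAnnotation
from regdiff.preprocess import (
    AdjustedGeneData,
    SplitAssignment,
    UntestableGeneError,
    cis_window,
    extract_cis,
    make_splits,
    residualize,
    standardize_and_prune,
)
from regdiff.simulate import sim_genotypes

IDS = [f"s{i}" for i in range(60)]


class TestMakeSplits:
    def test_thirds_of_nine(self):
        split = make_splits([f"s{i}" for i in range(9)], mode="thirds", seed=1)
        assert split.n_train == 3 and split.n_test == 3
        all_idx = np.concatenate([split.idx_a, split.idx_b, split.idx_t])
        assert len(set(all_idx.tolist())) == 9

    def test_full_overlap(self):
        split = make_splits(IDS, mode="auto", seed=2, overlap_fraction=1.0)
        assert set(split.idx_a.tolist()) == set(split.idx_b.tolist())
        assert not set(split.idx_t.tolist()) & set(split.idx_a.tolist())

    def test_determinism(self):
        s1 = make_splits(IDS, seed=5)
        s2 = make_splits(IDS, seed=5)
        np.testing.assert_array_equal(s1.idx_a, s2.idx_a)
        np.testing.assert_array_equal(s1.idx_t, s2.idx_t)
        s3 = make_splits(IDS, seed=6)
        assert not np.array_equal(s1.idx_a, s3.idx_a)

    def test_custom_violations_rejected(self):
        with pytest.raises(ValueError, match="equal size"):
            make_splits(IDS, mode="custom", custom=([0, 1], [2], [3]))
        with pytest.raises(ValueError, match="test set overlaps"):
            make_splits(IDS, mode="custom", custom=([0, 1], [2, 3], [1, 4]))
        with pytest.raises(ValueError, match="overlap"):
            make_splits(IDS, mode="custom", custom=([0, 1], [1, 2], [3, 4]))

    def test_explicit_sizes(self):
        split = make_splits(IDS, mode="auto", seed=0, n_train=20, n_test=15)
        assert split.n_train == 20 and split.n_test == 15

    @pytest.mark.parametrize("overlap", [0.0, 0.25, 0.5, 1.0])
    def test_invariants_hold(self, overlap):
        split = make_splits(IDS, mode="auto", seed=3, overlap_fraction=overlap)
        split.validate()  # raises on violation
        shared = len(set(split.idx_a.tolist()) & set(split.idx_b.tolist()))
        assert shared == round(overlap * split.n_train)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_splits(["a"] * 8)


class TestCisWindow:
    def test_arithmetic(self):
        g = GeneAnnotation.canonical("g", "5", 600_000, 610_000)
        assert cis_window(g, 500_000) == ("5", 100_000, 1_110_000)

    def test_lower_clip(self):
        g = GeneAnnotation.canonical("g", "1", 100, 200)
        assert cis_window(g, 500_000) == ("1", 1, 500_200)

    def test_zero_window_identity(self):
        g = GeneAnnotation.canonical("g", "1", 1000, 2000)
        assert cis_window(g, 0) == ("1", 1000, 2000)


class TestExtractCis:
    def test_boundary_inclusive(self):
        G = sim_genotypes(10, 5, 0.5, seed=1, start_pos=100, pos_step=100)
        # positions 100..500; closed interval [100, 300]
        sub = extract_cis(G, ("1", 100, 300))
        assert list(sub.variants["pos"]) == [100, 200, 300]

    def test_other_chromosome_excluded(self):
        G = sim_genotypes(10, 3, 0.5, seed=1, chrom="2")
        sub = extract_cis(G, ("1", 0, 10**9))
        assert sub.n_variants == 0

    def test_matches_linear_scan(self, rng):
        G = sim_genotypes(5, 50, 0.5, seed=2, start_pos=0, pos_step=37)
        lo, hi = 200, 900
        sub = extract_cis(G, ("1", lo, hi))
        expected = [
            G.variants["id"][j]
            for j in range(50)
            if lo <= G.variants["pos"][j] <= hi
        ]
        assert list(sub.variants["id"]) == expected


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        v = rng.normal(size=(15, 2))
        res = residualize(v, None)
        np.testing.assert_allclose(res, v - v.mean(axis=0), atol=1e-12)

    def test_perfect_fit(self, rng):
        c = rng.normal(size=20)
        res = residualize(c.copy(), c[:, None])
        np.testing.assert_allclose(res, 0, atol=1e-10)

    def test_normal_equations_oracle(self, rng):
        V = rng.normal(size=(20, 4))
        C = rng.normal(size=(20, 3))
        D = np.column_stack([np.ones(20), C])
        beta = np.linalg.solve(D.T @ D, D.T @ V)
        np.testing.assert_allclose(residualize(V, C), V - D @ beta, atol=1e-10)

    def test_orthogonal_to_covariates(self, rng):
        V = rng.normal(size=(30, 2))
        C = rng.normal(size=(30, 3))
        res = residualize(V, C)
        assert np.max(np.abs(C.T @ res)) < 1e-8 * np.max(np.abs(V))

    def test_idempotent(self, rng):
        V = rng.normal(size=(25, 3))
        C = rng.normal(size=(25, 2))
        once = residualize(V, C)
        np.testing.assert_allclose(residualize(once, C), once, atol=1e-10)

    def test_rank_deficient_warns_but_projects(self, rng):
        c = rng.normal(size=30)
        C = np.column_stack([c, 2 * c])
        V = rng.normal(size=(30, 1))
        with pytest.warns(UserWarning, match="rank deficient"):
            res = residualize(V, C)
        np.testing.assert_allclose(residualize(V, c[:, None]), res, atol=1e-10)


def _split_data(rng, n=30, p=6):
    out_x, out_y, covs = {}, {}, {}
    for s in ("A", "B", "T"):
        out_x[s] = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        out_y[s] = rng.normal(size=n)
        covs[s] = rng.normal(size=(n, 2))
    return out_x, out_y, covs


class TestStandardizeAndPrune:
    def test_constant_in_one_split_removed_everywhere(self, rng):
        raw_x, raw_y, covs = _split_data(rng)
        raw_x["T"][:, 2] = 1.0  # monomorphic in T only
        adj = standardize_and_prune(raw_x, raw_y, covs, [f"v{j}" for j in range(6)])
        assert "v2" not in adj.variant_ids
        assert adj.x_a.shape[1] == adj.x_b.shape[1] == adj.x_t.shape[1] == 5

    def test_post_moments(self, rng):
        raw_x, raw_y, covs = _split_data(rng)
        adj = standardize_and_prune(raw_x, raw_y, covs, [f"v{j}" for j in range(6)])
        for X, y in ((adj.x_a, adj.y_a), (adj.x_b, adj.y_b), (adj.x_t, adj.y_t)):
            assert np.max(np.abs(X.mean(axis=0))) < 1e-10
            np.testing.assert_allclose(X.var(axis=0, ddof=1), 1.0, atol=1e-8)
            assert abs(y.mean()) < 1e-10
            assert abs(y.var(ddof=1) - 1.0) < 1e-8

    def test_pruning_matches_scan_oracle(self, rng):
        raw_x, raw_y, covs = _split_data(rng, p=10)
        raw_x["A"][:, 4] = 2.0
        raw_x["B"][:, 7] = 0.0
        adj = standardize_and_prune(raw_x, raw_y, covs, [f"v{j}" for j in range(10)])
        expected = [
            f"v{j}"
            for j in range(10)
            if all(np.std(raw_x[s][:, j]) > 0 for s in ("A", "B", "T"))
        ]
        assert list(adj.variant_ids) == expected

    def test_constant_expression_untestable(self, rng):
        raw_x, raw_y, covs = _split_data(rng)
        raw_y["B"] = np.ones(30)
        with pytest.raises(UntestableGeneError):
            standardize_and_prune(raw_x, raw_y, covs, [f"v{j}" for j in range(6)])

    def test_split_independence(self, rng):
        """Perturbing one split leaves the others' adjusted data unchanged."""
        raw_x, raw_y, covs = _split_data(rng)
        ids = [f"v{j}" for j in range(6)]
        base = standardize_and_prune(raw_x, raw_y, covs, ids)
        raw_y2 = dict(raw_y)
        raw_y2["A"] = raw_y["A"] + rng.normal(size=30)
        perturbed = standardize_and_prune(raw_x, raw_y2, covs, ids)
        np.testing.assert_array_equal(base.x_b, perturbed.x_b)
        np.testing.assert_array_equal(base.y_t, perturbed.y_t)
        assert not np.array_equal(base.y_a, perturbed.y_a)
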