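import numpy as np
import pandas as pd
import pytest

import connlife as cl
from connlife.pls import _split_similarities, _zscore_cols, _cross_corr


def make_input(X, Y):
    return cl.PLSInput(X, Y, [f"x{i}" for i in range(X.shape[1])],
                       [f"y{i}" for i in range(Y.shape[1])])


def rank_one_input(n=60, p=12, support=4, noise=0.05, seed=0):
    """X whose first `support` columns follow a latent driven by Y."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    Y = np.column_stack([latent + noise * rng.standard_normal(n),
                         -latent + noise * rng.standard_normal(n)])
    X = noise * rng.standard_normal((n, p))
    X[:, :support] += latent[:, None]
    return make_input(X, Y), np.arange(p) < support


class TestFit:
    def test_identical_columns_give_single_perfect_lv(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(10)
        X = np.column_stack([col, col])
        inp = make_input(X, X.copy())
        model = cl.pls_fit(inp)
        np.testing.assert_allclose(model.S, [2.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(model.R, np.ones((2, 2)), atol=1e-12)

    def test_independent_noise_shrinks_correlations(self):
        rng = np.random.default_rng(2)
        inp = make_input(rng.standard_normal((2000, 5)),
                         rng.standard_normal((2000, 2)))
        model = cl.pls_fit(inp)
        assert np.abs(model.R).max() < 0.1
        assert model.S.max() < 0.2

    def test_singular_values_match_eigen_oracle(self):
        rng = np.random.default_rng(3)
        inp = make_input(rng.standard_normal((6, 3)),
                         rng.standard_normal((6, 2)))
        model = cl.pls_fit(inp)
        eigvals = np.linalg.eigvalsh(model.R @ model.R.T)[::-1]
        np.testing.assert_allclose(model.S, np.sqrt(np.clip(eigvals, 0, None)),
                                   atol=1e-10)

    def test_reconstruction(self):
        rng = np.random.default_rng(4)
        inp = make_input(rng.standard_normal((25, 8)),
                         rng.standard_normal((25, 2)))
        model = cl.pls_fit(inp)
        np.testing.assert_allclose(model.U @ np.diag(model.S) @ model.V.T,
                                   model.R, atol=1e-10)
        # orthonormal saliences
        np.testing.assert_allclose(model.U.T @ model.U, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.V.T @ model.V, np.eye(2), atol=1e-10)

    def test_sign_convention(self):
        inp, _ = rank_one_input(seed=5)
        model = cl.pls_fit(inp)
        for k in range(model.n_lv):
            j = np.argmax(np.abs(model.U[:, k]))
            assert model.U[j, k] > 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        a = cl.pls_fit(make_input(X, Y))
        X2 = X.copy()
        X2[:, 0] *= 37.5
        b = cl.pls_fit(make_input(X2, Y))
        np.testing.assert_allclose(a.R, b.R, atol=1e-12)
        np.testing.assert_allclose(a.S, b.S, atol=1e-12)

    def test_constant_behavior_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 3))
        Y = np.column_stack([rng.standard_normal(10), np.ones(10)])
        with pytest.raises(ValueError, match="constant behavior"):
            cl.pls_fit(make_input(X, Y))

    def test_zero_variance_brain_column_dropped(self):
        import warnings as _warnings
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.2
        with _warnings.catch_warnings():
            _warnings.simplefilter("always")
            with pytest.warns(UserWarning, match="zero-variance"):
                inp = make_input(X, rng.standard_normal((10, 2)))
        assert inp.X.shape[1] == 2
        assert inp.dropped == ["x1"]


class TestPermutation:
    def test_strong_signal_significant(self):
        inp, _ = rank_one_input(n=80, seed=9)
        model = cl.pls_fit(inp)
        res = cl.permutation_test(inp, model, n_perm=200, seed=0)
        assert res.p[0] <= 0.01

    def test_counting_formula_floor(self):
        inp, _ = rank_one_input(n=80, noise=0.01, seed=10)
        model = cl.pls_fit(inp)
        res = cl.permutation_test(inp, model, n_perm=19, seed=0)
        # all permuted top singular values below the observed one
        assert res.p[0] == pytest.approx(1 / 20)

    def test_deterministic_and_min_perms(self):
        inp, _ = rank_one_input(seed=11)
        model = cl.pls_fit(inp)
        a = cl.permutation_test(inp, model, n_perm=50, seed=3).p
        b = cl.permutation_test(inp, model, n_perm=50, seed=3).p
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            cl.permutation_test(inp, model, n_perm=10)


class TestBootstrap:
    def test_recovers_planted_support(self):
        inp, support = rank_one_input(n=100, noise=0.05, seed=12)
        model = cl.pls_fit(inp)
        boot = cl.bootstrap_ratios(inp, model, n_boot=200, seed=0)
        b1 = np.abs(boot.bsr[:, 0])
        assert b1[support].min() >= 10
        assert np.mean(b1[~support] < 2) >= 0.5

    def test_identical_subjects_degenerate(self):
        # all-identical subjects: every brain variable is constant, so
        # the input itself is refused as degenerate
        X = np.tile([[1.0, 2.0, 3.0]], (10, 1))
        Y = np.tile([[1.0, 0.0]], (10, 1))
        with pytest.raises(ValueError):
            make_input(X, Y)

    def test_redraw_exhaustion_errors(self):
        # Y nearly constant: most bootstrap draws miss the single
        # distinct subject and produce a constant behavior column
        rng = np.random.default_rng(30)
        n = 12
        X = rng.standard_normal((n, 3))
        Y = np.tile([[1.0, 0.0]], (n, 1))
        Y[0] = [2.0, 1.0]
        inp = make_input(X, Y)
        model = cl.pls_fit(inp)
        with pytest.raises(RuntimeError, match="constant columns"):
            cl.bootstrap_ratios(inp, model, n_boot=500, seed=0,
                                max_redraws=0)

    def test_doubling_boots_stable(self):
        inp, support = rank_one_input(n=100, seed=13)
        model = cl.pls_fit(inp)
        a = cl.bootstrap_ratios(inp, model, n_boot=250, seed=1).bsr[:, 0]
        b = cl.bootstrap_ratios(inp, model, n_boot=500, seed=1).bsr[:, 0]
        # support BSRs agree within Monte-Carlo error (relative)
        ratio = a[support] / b[support]
        assert np.all(np.abs(ratio - 1) < 0.5)

    def test_ci_covers_point_estimate(self):
        inp, _ = rank_one_input(n=100, seed=14)
        model = cl.pls_fit(inp)
        boot = cl.bootstrap_ratios(inp, model, n_boot=200, seed=2)
        r0 = model.lv_behavior_corr[0]
        assert np.all(boot.corr_ci[0, :, 0] <= r0 + 0.1)
        assert np.all(boot.corr_ci[0, :, 1] >= r0 - 0.1)


class TestSplitHalf:
    def test_duplicated_subjects_give_perfect_similarity(self):
        # force the split so each half is one exact copy of the cohort
        class IdentitySplit:
            def permutation(self, n):
                return np.arange(n)

        inp, _ = rank_one_input(n=30, seed=15)
        Xd = np.vstack([inp.X, inp.X])
        Yd = np.vstack([inp.Y, inp.Y])
        Xz, Yz = _zscore_cols(Xd), _zscore_cols(Yd)
        S_full = np.linalg.svd(_cross_corr(Xz, Yz), compute_uv=False)
        sval, svec = _split_similarities(Xz, Yz, S_full, IdentitySplit(),
                                         n_splits=3)
        np.testing.assert_allclose(svec, 1.0, atol=1e-10)
        np.testing.assert_allclose(sval, 1.0, atol=1e-10)

    def test_planted_signal_reproducible(self):
        inp, _ = rank_one_input(n=120, seed=16)
        res = cl.split_half(inp, n_splits=100, seed=0, n_null_perm=3)
        assert res.z_svec[0] > res.svec_threshold[0]
        assert bool(res.reproducible[0])

    def test_needs_eight_subjects(self):
        rng = np.random.default_rng(17)
        inp = make_input(rng.standard_normal((6, 4)),
                         rng.standard_normal((6, 2)))
        with pytest.raises(ValueError, match="at least 8"):
            cl.split_half(inp, n_splits=10, seed=0)


class TestReliablePattern:
    def _edge_setup(self, bsrs, edges, n_regions=6):
        half = n_regions // 2
        regions = pd.DataFrame({
            "label": [f"r{k}" for k in range(n_regions)],
            "hemisphere": ["L"] * half + ["R"] * half,
            "subcortical": 0,
        })
        p = len(bsrs)
        model = cl.PLSModel(
            R=np.zeros((2, p)), U=np.eye(2), S=np.array([1.0, 0.5]),
            V=np.zeros((p, 2)), brain_scores=np.zeros((3, 2)),
            behavior_scores=np.zeros((3, 2)),
            lv_behavior_corr=np.zeros((2, 2)),
            x_labels=[f"e{k}" for k in range(p)], y_labels=["age", "fi"],
            n=3)
        boot = cl.pls.BootstrapResult(
            bsr=np.column_stack([bsrs, np.zeros(p)]),
            se=np.ones((p, 2)), corr_ci=np.zeros((2, 2, 2)), n_boot=100,
            n_redraws=0)
        return model, boot, regions, np.array(edges)

    def test_intrahemispheric_percentages(self):
        bsrs = [3.0, 4.0, 5.0, 2.5, 2.1]
        edges = [(0, 1), (0, 2), (1, 2), (0, 1), (1, 2)]  # all within L
        model, boot, regions, edge_index = self._edge_setup(bsrs, edges)
        pat = cl.reliable_pattern(model, boot, lv=0, bsr_threshold=2.0,
                                  region_metadata=regions,
                                  edge_index=edge_index)
        assert pat.pct_intra == pytest.approx(100.0)
        assert pat.pct_intra_left == pytest.approx(100.0)
        assert pat.pct_inter == pytest.approx(0.0)

    def test_hub_needs_degree_above_three(self):
        bsrs = [3.0, 3.0, 3.0, 3.0]
        edges = [(0, 1), (0, 2), (0, 3), (0, 4)]  # region 0 degree 4
        model, boot, regions, edge_index = self._edge_setup(bsrs, edges)
        pat = cl.reliable_pattern(model, boot, lv=0, bsr_threshold=2.0,
                                  region_metadata=regions,
                                  edge_index=edge_index)
        assert pat.hubs == ["r0"]

    def test_empty_selection_no_error(self):
        model, boot, regions, edge_index = self._edge_setup(
            [1.0, -1.5], [(0, 1), (2, 3)])
        pat = cl.reliable_pattern(model, boot, lv=0, bsr_threshold=50.0,
                                  region_metadata=regions,
                                  edge_index=edge_index)
        assert len(pat.variables) == 0
        assert pat.hubs == []

    def test_nonpositive_threshold_rejected(self):
        model, boot, regions, edge_index = self._edge_setup(
            [1.0], [(0, 1)])
        with pytest.raises(ValueError):
            cl.reliable_pattern(model, boot, lv=0, bsr_threshold=0.0)
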