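"""Hierarchical sparsity, proximal training and Granger detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import glacier.granger as gg
from glacier import (
    GrangerModel,
    SpatialDAG,
    SpatialExpressionDataset,
    TrainConfig,
    build_lag_operators,
    estimate_lag,
    fit_single_lambda,
    hierarchical_penalty,
    lambda_validity,
    prox_hierarchical,
    stratified_partition,
    var_granger_oracle,
)
from glacier.data import DataValidationError, NormalizedExpression


def numerical_prox(v: np.ndarray, t: float, n_iter: int = 4000) -> np.ndarray:
    """Independent oracle: Dykstra's proximal splitting for the prox of a sum
    of convex terms, each term being one suffix-group norm whose own prox is
    plain group soft-thresholding.  Makes no use of the nesting structure."""
    L, d = v.shape

    def group_soft(x, l):
        out = x.copy()
        n = np.linalg.norm(x[l:])
        out[l:] = 0.0 if n <= t else x[l:] * (1 - t / n)
        return out

    x = v.copy()
    p = [np.zeros_like(v) for _ in range(L)]
    for _ in range(n_iter):
        for l in range(L):
            y = group_soft(x + p[l], l)
            p[l] = x + p[l] - y
            x = y
    return x


def path_ops(n: int, max_lag: int):
    dag = SpatialDAG(
        n_vertices=n, edges=np.array([[i, i + 1] for i in range(n - 1)])
    )
    return build_lag_operators(dag, max_lag)


class TestPenalty:
    def test_zero_weights_zero_penalty(self):
        assert hierarchical_penalty(np.zeros((3, 4)), 2.0) == 0.0

    def test_single_lag_is_plain_norm(self):
        assert hierarchical_penalty(np.array([[3.0]]), 2.0) == pytest.approx(6.0)

    def test_nested_groups_hand_computed(self):
        # groups: (lag1, lag2) with norm 5 and (lag2) with norm 4
        W = np.array([[3.0, 0.0], [0.0, 4.0]])
        assert hierarchical_penalty(W, 1.0) == pytest.approx(9.0)
        assert hierarchical_penalty(W, 0.5) == pytest.approx(4.5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_penalty(np.ones((1, 1)), -1.0)


class TestProx:
    def test_zero_threshold_identity(self):
        v = np.random.default_rng(0).normal(size=(3, 2, 4))
        np.testing.assert_array_equal(prox_hierarchical(v, 0.0), v)

    def test_huge_threshold_zeroes_everything(self):
        v = np.random.default_rng(1).normal(size=(3, 2, 4))
        np.testing.assert_array_equal(
            prox_hierarchical(v, 1e6), np.zeros_like(v)
        )

    def test_single_group_soft_threshold(self):
        out = prox_hierarchical(np.array([[3.0, 4.0]]), 2.0)
        np.testing.assert_allclose(out, [[1.8, 2.4]])

    def test_matches_numerical_minimization(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            L = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            v = rng.normal(0, 2, (L, d))
            t = float(rng.uniform(0, 3))
            got = prox_hierarchical(v, t)
            ref = numerical_prox(v, t)
            worst = max(worst, float(np.abs(got - ref).max()))
        assert worst <= 1e-6

    def test_non_expansive(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            u = rng.normal(size=(3, 5))
            v = rng.normal(size=(3, 5))
            t = float(rng.uniform(0, 2))
            lhs = np.linalg.norm(prox_hierarchical(u, t) - prox_hierarchical(v, t))
            assert lhs <= np.linalg.norm(u - v) + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_support_respects_nesting(self, seed):
        """If the suffix group l..L is zero after the prox, every lag >= l
        is zero (hierarchical support structure)."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 6))
        W = prox_hierarchical(rng.normal(size=(L, 3)), float(rng.uniform(0, 2)))
        nz = np.abs(W).max(axis=1) > 0
        # once a lag is zero, all longer lags must be zero too
        seen_zero = False
        for l in range(L):
            if not nz[l]:
                seen_zero = True
            elif seen_zero:
                # a nonzero lag after a zero one violates the suffix nesting
                # only if the zero arose from group elimination; the prox
                # zeroes suffixes, so this must not happen
                pytest.fail(f"nonzero lag {l + 1} after zeroed shorter lag")


class TestDesign:
    def test_path_lag_blocks(self):
        ops = path_ops(3, 2)
        norm = NormalizedExpression(
            values=np.array([[1.0], [2.0], [3.0]]), scheme="none", gene_names=["x"]
        )
        design = gg.assemble_design(norm, ["x"], ops)
        np.testing.assert_allclose(design[0][:, 0], [0, 1, 2])
        np.testing.assert_allclose(design[1][:, 0], [0, 0, 1])

    def test_diamond_block_averages_parents(self):
        dag = SpatialDAG(
            n_vertices=4, edges=np.array([[0, 1], [0, 2], [1, 3], [2, 3]])
        )
        ops = build_lag_operators(dag, 2)
        x = np.array([[5.0], [1.0], [3.0], [9.0]])
        norm = NormalizedExpression(values=x, scheme="none", gene_names=["x"])
        design = gg.assemble_design(norm, ["x"], ops)
        assert design[0][3, 0] == pytest.approx((1.0 + 3.0) / 2)
        assert design[1][3, 0] == pytest.approx(5.0)

    def test_empty_regulators_rejected(self):
        ops = path_ops(3, 1)
        norm = NormalizedExpression(
            values=np.zeros((3, 1)), scheme="none", gene_names=["x"]
        )
        with pytest.raises(DataValidationError):
            gg.assemble_design(norm, [], ops)


class TestValidityAndLag:
    def _model_with_fraction(self, frac: float) -> GrangerModel:
        W = np.zeros((2, 5, 10))
        flat = W.reshape(-1)
        flat[: int(round(frac * flat.size))] = 1.0
        return GrangerModel(
            W1=W, b1=np.zeros(4), W2=np.zeros(4), b2=0.0
        )

    @pytest.mark.parametrize(
        "frac,valid",
        [(0.0, False), (0.04, False), (0.05, False), (0.5, True),
         (0.95, False), (0.96, False), (1.0, False)],
    )
    def test_validity_band_strict_inside(self, frac, valid):
        assert lambda_validity(self._model_with_fraction(frac)) is valid

    def test_lag_largest_nonzero_block(self):
        W = np.zeros((5, 1, 3))
        W[0, 0, 1] = 1.0
        m = GrangerModel(W1=W, b1=np.zeros(3), W2=np.zeros(3), b2=0.0)
        assert estimate_lag(m, 0) == 1
        W[2, 0, 0] = 0.5
        assert estimate_lag(m, 0) == 3
        assert estimate_lag(
            GrangerModel(W1=np.zeros((5, 1, 3)), b1=np.zeros(3),
                         W2=np.zeros(3), b2=0.0), 0
        ) == 0


class TestFitting:
    def test_noise_target_fully_pruned(self):
        rng = np.random.default_rng(0)
        n = 400
        ops = path_ops(n, 2)
        X = rng.normal(size=(n, 2))
        design = np.stack([ops.apply(l, X) for l in (1, 2)])
        y = rng.normal(size=n)  # independent of regulators
        cfg = TrainConfig(learning_rate=0.1, epochs=2000, max_lag=2, seed=0)
        model, _ = fit_single_lambda(design, y, cfg, lam=0.3, seed=1)
        assert model.nonzero_fraction() == 0.0

    def test_planted_regulator_dominates_decoy(self):
        rng = np.random.default_rng(3)
        n = 500
        ops = path_ops(n, 3)
        x_true = rng.normal(size=n)
        x_decoy = rng.normal(size=n)
        y = 0.9 * np.concatenate([[0], x_true[:-1]]) + 0.05 * rng.normal(size=n)
        design = np.stack(
            [ops.apply(l, np.column_stack([x_true, x_decoy])) for l in (1, 2, 3)]
        )
        cfg = TrainConfig(learning_rate=0.1, epochs=3000, max_lag=3, seed=0)
        model, _ = fit_single_lambda(design, y, cfg, lam=0.05, seed=2)
        assert model.group_norm(0) >= 10 * max(model.group_norm(1), 1e-12)

    def test_lambda0_linear_matches_ols(self):
        rng = np.random.default_rng(5)
        n = 300
        ops = path_ops(n, 3)
        x = rng.normal(size=n)
        y = 0.7 * np.concatenate([[0], x[:-1]]) + 0.1 * rng.normal(size=n)
        design = np.stack([ops.apply(l, x[:, None]) for l in (1, 2, 3)])
        cfg = TrainConfig(
            learning_rate=0.05, epochs=8000, max_lag=3, seed=0,
            activation="linear", scheduler="none", patience=5000,
        )
        model, _ = fit_single_lambda(design, y, cfg, lam=0.0, seed=4)
        pred = model.forward(design)
        X = np.column_stack([design[l, :, 0] for l in range(3)] + [np.ones(n)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.abs(pred - X @ beta).max() < 1e-4

    def test_identical_seed_identical_weights(self):
        rng = np.random.default_rng(1)
        n = 200
        ops = path_ops(n, 2)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        design = np.stack([ops.apply(l, x[:, None]) for l in (1, 2)])
        cfg = TrainConfig(learning_rate=0.1, epochs=500, max_lag=2, seed=0)
        m1, _ = fit_single_lambda(design, y, cfg, lam=0.01, seed=9)
        m2, _ = fit_single_lambda(design, y, cfg, lam=0.01, seed=9)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)

    def test_loss_trace_tail_non_increasing(self):
        rng = np.random.default_rng(2)
        n = 300
        ops = path_ops(n, 2)
        x = rng.normal(size=n)
        y = 0.5 * np.concatenate([[0], x[:-1]]) + 0.1 * rng.normal(size=n)
        design = np.stack([ops.apply(l, x[:, None]) for l in (1, 2)])
        cfg = TrainConfig(learning_rate=0.1, epochs=8000, max_lag=2, seed=0)
        _, diag = fit_single_lambda(design, y, cfg, lam=0.02, seed=3)
        assert diag.monotone_tail


class TestSweep:
    def _setup(self):
        rng = np.random.default_rng(11)
        n = 300
        ops = path_ops(n, 2)
        x = rng.normal(size=(n, 2))
        y = 0.8 * np.concatenate([[0], x[:-1, 0]]) + 0.1 * rng.normal(size=n)
        design = np.stack([ops.apply(l, x) for l in (1, 2)])
        return design, y

    def test_single_valid_lambda_equals_that_run(self):
        design, y = self._setup()
        lam = 0.05
        cfg = TrainConfig(
            learning_rate=0.1, epochs=2000, max_lag=2, seed=0,
            lambda_grid=[lam],
        )
        res = gg.sweep_and_ensemble(design, y, ["a", "b"], cfg, seed=5)
        seed = int(np.random.SeedSequence([5, 0]).generate_state(1)[0] % (2**31))
        model, _ = fit_single_lambda(design, y, cfg, lam, seed=seed)
        assert res.n_valid == 1
        assert res.scores["a"] == pytest.approx(model.group_norm(0))
        assert res.scores["b"] == pytest.approx(model.group_norm(1))

    def test_two_valid_lambdas_average(self):
        design, y = self._setup()
        cfg = TrainConfig(
            learning_rate=0.1, epochs=2000, max_lag=2, seed=0,
            lambda_grid=[0.05, 0.08],
        )
        res = gg.sweep_and_ensemble(design, y, ["a", "b"], cfg, seed=5)
        if res.n_valid == 2:  # both settings valid under the band
            per = []
            for i, lam in enumerate([0.05, 0.08]):
                seed = int(
                    np.random.SeedSequence([5, i]).generate_state(1)[0] % (2**31)
                )
                m, _ = fit_single_lambda(design, y, cfg, lam, seed=seed)
                per.append(m.group_norm(0))
            assert res.scores["a"] == pytest.approx(np.mean(per))

    def test_all_invalid_raises_with_fractions(self):
        design, y = self._setup()
        cfg = TrainConfig(
            learning_rate=0.1, epochs=300, max_lag=2, seed=0,
            lambda_grid=[1e-7],  # no pruning at all -> saturated
        )
        with pytest.raises(DataValidationError, match="broader range"):
            gg.sweep_and_ensemble(design, y, ["a", "b"], cfg, seed=5)


class TestStratifiedPartition:
    def _dataset(self, labels):
        n = len(labels)
        return SpatialExpressionDataset(
            counts=np.ones((n, 1), dtype=int),
            coords=np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
            gene_names=["g"],
            cell_labels=np.array(labels),
        )

    def test_balanced_three_by_three(self):
        ds = self._dataset(["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        parts = stratified_partition(ds, 3, seed=0)
        for p in parts:
            assert sorted(np.unique(p.cell_labels)) == ["a", "b", "c"]
            assert p.n_cells == 3

    def test_disjoint_cover(self):
        labels = ["a"] * 7 + ["b"] * 5
        parts = stratified_partition(self._dataset(labels), 3, seed=1)
        ids = np.concatenate([p.cell_ids for p in parts])
        assert sorted(ids) == list(range(12))

    def test_remainder_sizes(self):
        parts = stratified_partition(self._dataset(["a"] * 10), 3, seed=2)
        assert sorted(p.n_cells for p in parts) == [3, 3, 4]

    def test_missing_labels_rejected(self):
        ds = self._dataset(["a"] * 6)
        ds.cell_labels = None
        with pytest.raises(DataValidationError):
            stratified_partition(ds, 3)


class TestVAROracle:
    def test_detects_lagged_dependence(self):
        rng = np.random.default_rng(0)
        T = 500
        x = rng.normal(size=T)
        y = np.zeros(T)
        for t in range(1, T):
            y[t] = 0.8 * x[t - 1] + 0.2 * rng.normal()
        assert var_granger_oracle(x, y, 3, 0.01).causal

    def test_autoregressive_only_not_causal(self):
        rng = np.random.default_rng(4)
        T = 500
        x = rng.normal(size=T)
        y = np.zeros(T)
        for t in range(1, T):
            y[t] = 0.9 * y[t - 1] + 0.3 * rng.normal()
        assert not var_granger_oracle(x, y, 3, 0.01).causal

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        alpha = 0.05
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=300)
            y = rng.normal(size=300)
            rejections += var_granger_oracle(x, y, 2, alpha).causal
        # binomial 99% interval around alpha * n_rep
        se = np.sqrt(n_rep * alpha * (1 - alpha))
        assert abs(rejections - n_rep * alpha) <= 2.58 * se

    def test_matches_statsmodels_f_test(self):
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(12)
        T = 200
        x = rng.normal(size=T)
        y = 0.5 * np.concatenate([[0], x[:-1]]) + rng.normal(size=T)
        ours = var_granger_oracle(x, y, 2, 0.05)
        sm = grangercausalitytests(
            np.column_stack([y, x]), maxlag=[2], verbose=False
        )[2][0]["ssr_ftest"]
        assert ours.f_stat == pytest.approx(sm[0], rel=1e-6)
        assert ours.p_value == pytest.approx(sm[1], abs=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(DataValidationError):
            var_granger_oracle(np.zeros(8), np.zeros(8), 3)
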