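"""DAG-structured Granger causal inference with hierarchical lag sparsity.

A target gene's expression at each vertex is predicted from candidate
regulators' expression aggregated over 1..L-step graph ancestors.  The first
layer of the prediction network carries one weight block per regulator per
lag; a nested group-lasso penalty over lag suffixes (lags l..L for every l)
penalizes longer lags more heavily, and training interleaves adaptive
gradient steps with the exact proximal operator of that penalty, yielding
exact zeros.  A regulator Granger-causes the target when its first-layer
weights survive regularization (invariance-based detection); scores are
ensembled across the valid part of a lambda grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._optim import Adam
from .dag import LagOperators, SpatialDAG, build_knn_graph, build_lag_operators, orient_edges
from .data import (
    CandidatePairList,
    DataValidationError,
    InteractionTable,
    NormalizedExpression,
    SpatialExpressionDataset,
    normalize_expression,
)
from .isodepth import IsodepthField, invert_isodepth

logger = logging.getLogger("glacier")

ZERO_TOL = 1e-8


@dataclass
class TrainConfig:
    """Hyperparameters for Granger-model training.

    Defaults follow sparse-UMI practice: learning rate 0.1 for TF-target
    analysis (use 0.01 for ligand-receptor), up to 10,000 epochs with an
    optional plateau scheduler, and a lambda grid of 30 log-spaced values in
    [0.001, 0.1].  A lambda setting is *valid* when the fraction of nonzero
    first-layer weights lies strictly between ``validity_band``.
    """

    learning_rate: float = 0.1
    epochs: int = 10_000
    lambda_grid: Optional[Sequence[float]] = None
    lambda_count: int = 30
    lambda_range: tuple[float, float] = (0.001, 0.1)
    validity_band: tuple[float, float] = (0.05, 0.95)
    max_lag: int = 5
    hidden_width: int = 16
    activation: str = "tanh"
    seed: int = 0
    scheduler: str = "plateau"
    include_self_lags: bool = True
    normalization: str = "log_cpm_z"
    k_neighbors: int = 7
    early_stop_rtol: float = 1e-7
    patience: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.validity_band
        if not 0 < lo < hi < 1:
            raise ValueError("validity band must satisfy 0 < low < high < 1")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if (grid <= 0).any() or (np.diff(grid) < 0).any():
                raise ValueError("lambda_grid must be positive and sorted")

    def grid(self) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.asarray(self.lambda_grid, dtype=float)
        lo, hi = self.lambda_range
        return np.geomspace(lo, hi, self.lambda_count)


@dataclass
class GrangerModel:
    """First-layer lag/regulator weight blocks plus a small dense head."""

    W1: np.ndarray  # (L, R, d) penalized blocks
    b1: np.ndarray  # (d,)
    W2: np.ndarray  # (d,)
    b2: float
    activation: str = "tanh"
    w_self: Optional[np.ndarray] = None  # (d,), unpenalized own-past term
    regulators: list[str] = dc_field(default_factory=list)

    @property
    def max_lag(self) -> int:
        return self.W1.shape[0]

    def forward(
        self, design: np.ndarray, y_lag: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """design: (L, N, R) lagged regulator blocks; returns (N,) predictions."""
        pre = np.einsum("lnr,lrd->nd", design, self.W1) + self.b1
        if self.w_self is not None and y_lag is not None:
            pre = pre + np.outer(y_lag, self.w_self)
        H = np.tanh(pre) if self.activation == "tanh" else pre
        return H @ self.W2 + self.b2

    def group_norm(self, r: int) -> float:
        """Full-lag-group norm of regulator r's first-layer weights."""
        return float(np.linalg.norm(self.W1[:, r, :]))

    def nonzero_fraction(self) -> float:
        return float(np.mean(np.abs(self.W1) > ZERO_TOL))


def hierarchical_penalty(weights: np.ndarray, lam: float) -> float:
    """Nested group-lasso penalty for one regulator's (L, d) weight blocks.

    Sum over l = 1..L of ``lam * ||(w_l, ..., w_L)||_2``: lag l appears in l
    nested suffix groups, so longer lags are penalized more heavily.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    return lam * sum(
        float(np.linalg.norm(W[l:])) for l in range(W.shape[0])
    )


def prox_hierarchical(weights: np.ndarray, threshold: float) -> np.ndarray:
    """Exact proximal operator of the nested suffix-group penalty.

    Accepts (L, R, d) blocks (or (L, d) for a single regulator) and applies
    group soft-thresholding from the innermost group (lag L alone) outward to
    the full group (lags 1..L), independently per regulator.  This sequential
    scheme is the exact prox for tree-structured (nested) groups.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    W = np.asarray(weights, dtype=float).copy()
    single = W.ndim == 2
    if single:
        W = W[:, None, :]
    L = W.shape[0]
    for l in range(L, 0, -1):
        norms = np.sqrt((W[l - 1:] ** 2).sum(axis=(0, 2)))  # (R,)
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - threshold / np.where(norms > 0, norms, 1.0)), 0.0)
        W[l - 1:] *= scale[None, :, None]
    return W[:, 0, :] if single else W


def assemble_design(
    norm_expr: NormalizedExpression,
    regulators: Sequence[str],
    ops: LagOperators,
) -> np.ndarray:
    """Lagged design: block l aggregates regulator expression from l-step
    ancestors.  Returns (L, N, R); rows of vertices without l-step ancestors
    are zero in block l."""
    if not regulators:
        raise DataValidationError("empty regulator set")
    X = np.column_stack([norm_expr.column(g) for g in regulators])
    if ops.ops[0].shape[0] != X.shape[0]:
        raise DataValidationError("operators and expression disagree on N")
    return np.stack([ops.apply(l, X) for l in range(1, ops.max_lag + 1)])


def aggregate_self_lags(y: np.ndarray, ops: LagOperators) -> np.ndarray:
    """Own-past predictor: mean over lags of ancestor-aggregated target."""
    return np.mean([ops.apply(l, y) for l in range(1, ops.max_lag + 1)], axis=0)


@dataclass
class FitDiagnostics:
    loss_trace: np.ndarray
    nonzero_fraction: float
    lam: float
    learning_rate: float
    epochs_run: int
    converged: bool
    monotone_tail: bool


def _init_model(
    rng: np.random.Generator, L: int, R: int, d: int, activation: str,
    with_self: bool,
) -> GrangerModel:
    s1 = 1.0 / np.sqrt(max(1, L * R))
    return GrangerModel(
        W1=rng.normal(0, s1, (L, R, d)),
        b1=np.zeros(d),
        W2=rng.normal(0, 1.0 / np.sqrt(d), d),
        b2=0.0,
        activation=activation,
        w_self=rng.normal(0, 1.0, d) if with_self else None,
    )


def fit_single_lambda(
    design: np.ndarray,
    target: np.ndarray,
    cfg: TrainConfig,
    lam: float,
    y_lag: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> tuple[GrangerModel, FitDiagnostics]:
    """Train one model at one regularization strength.

    Full-batch adaptive gradient steps on the squared prediction error,
    each followed by the exact hierarchical prox on the first-layer blocks
    (threshold lambda * current learning rate), so surviving weights are
    exactly nonzero and pruned ones exactly zero.  A plateau scheduler
    halves the learning rate when the loss stalls; training stops early once
    the relative improvement falls below ``early_stop_rtol``.
    """
    if not np.isfinite(target).all():
        raise DataValidationError("target contains non-finite values")
    L, N, R = design.shape
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    with_self = cfg.include_self_lags and y_lag is not None
    model = _init_model(rng, L, R, cfg.hidden_width, cfg.activation, with_self)
    # The penalized first layer takes plain (ISTA-style) gradient steps so
    # that its update size tracks the true gradient and the prox threshold
    # lambda * lr retains its proximal-gradient meaning; the unpenalized
    # downstream layers use adaptive (Adam) steps for fast convergence.
    # With lambda = 0 there is no prox step, so the first layer joins the
    # adaptive group.
    b2 = np.array([model.b2])
    smooth = [model.b1, model.W2, b2] + ([model.w_self] if with_self else [])
    if lam == 0:
        smooth = [model.W1] + smooth
    opt = Adam(smooth, lr=cfg.learning_rate)
    lr = cfg.learning_rate

    losses = np.empty(cfg.epochs)
    best = np.inf
    best_seen = np.inf
    best_epoch = 0
    stall = 0
    epochs_run = cfg.epochs
    tanh = cfg.activation == "tanh"
    track = [model.W1, model.b1, model.W2, b2] + (
        [model.w_self] if with_self else []
    )
    snapshot = [p.copy() for p in track]
    # flatten (lag, regulator) so the first layer is a single BLAS matmul
    design2d = np.ascontiguousarray(design.transpose(1, 0, 2).reshape(N, L * R))

    for epoch in range(cfg.epochs):
        pre = design2d @ model.W1.reshape(L * R, -1) + model.b1
        if with_self:
            pre += np.outer(y_lag, model.w_self)
        H = np.tanh(pre) if tanh else pre
        yhat = H @ model.W2 + b2[0]
        resid = yhat - target
        mse = float(resid @ resid) / N
        if lam > 0:
            suffix = np.sqrt(
                np.cumsum((model.W1 ** 2).sum(axis=2)[::-1], axis=0)[::-1]
            ).sum()
            loss = mse + lam * float(suffix)
        else:
            loss = mse
        if not np.isfinite(loss):
            raise DataValidationError(
                f"training diverged (loss NaN/inf) at lambda={lam:g}, "
                f"eta={cfg.learning_rate:g}"
            )
        losses[epoch] = loss

        r = (2.0 / N) * resid
        dW2 = H.T @ r
        db2 = np.array([r.sum()])
        dH = np.outer(r, model.W2)
        dpre = dH * (1 - H * H) if tanh else dH
        dW1 = (design2d.T @ dpre).reshape(L, R, -1)
        db1 = dpre.sum(axis=0)
        opt.lr = lr
        grads = [db1, dW2, db2] + ([y_lag @ dpre] if with_self else [])
        if lam == 0:
            opt.step([dW1] + grads)
        else:
            opt.step(grads)
            model.W1 -= lr * dW1
            model.W1[...] = prox_hierarchical(model.W1, lam * lr)

        if cfg.scheduler == "plateau" and epoch == (9 * cfg.epochs) // 10:
            # terminal cooldown: a quiet tail for convergence diagnostics
            lr = min(lr, cfg.learning_rate * 0.02)
        if loss < best_seen:
            # keep the best iterate; full-batch adaptive steps can cycle
            # near the optimum and leave the final iterate worse
            best_seen = loss
            snapshot = [p.copy() for p in track]
        if loss < best * (1 - cfg.early_stop_rtol):
            best, best_epoch, stall = loss, epoch, 0
        else:
            stall += 1
            if cfg.scheduler == "plateau" and stall and stall % cfg.patience == 0:
                # decay damps late limit cycles; the floor keeps the prox
                # threshold meaningful (the best penalized iterate is kept,
                # so late dense iterates cannot leak into the result)
                lr = max(lr * 0.5, cfg.learning_rate * 0.01)
            if stall >= 4 * cfg.patience:
                epochs_run = epoch + 1
                break

    for p, s in zip(track, snapshot):
        p[...] = s
    model.b2 = float(b2[0])
    losses = losses[:epochs_run]
    tail = losses[-max(2, epochs_run // 10):]
    tol = 1e-3 * max(1.0, losses[0])
    monotone = bool(np.all(np.diff(tail) <= tol))
    diag = FitDiagnostics(
        loss_trace=losses,
        nonzero_fraction=model.nonzero_fraction(),
        lam=lam,
        learning_rate=cfg.learning_rate,
        epochs_run=epochs_run,
        converged=epochs_run < cfg.epochs,
        monotone_tail=monotone,
    )
    if not monotone:
        logger.debug("loss tail not monotone at lambda=%g", lam)
    return model, diag


def lambda_validity(model: GrangerModel, band: tuple[float, float] = (0.05, 0.95)) -> bool:
    """A fit is valid when some, but not almost all, first-layer weights
    survive: nonzero fraction strictly inside the band."""
    frac = model.nonzero_fraction()
    return band[0] < frac < band[1]


def estimate_lag(model: GrangerModel, regulator_index: int) -> int:
    """Largest lag whose weight block for this regulator has a surviving
    weight; 0 when the regulator was pruned entirely."""
    nz = np.abs(model.W1[:, regulator_index, :]).max(axis=1) > ZERO_TOL
    return int(np.max(np.flatnonzero(nz)) + 1) if nz.any() else 0


@dataclass
class SweepResult:
    scores: dict[str, float]
    lags: dict[str, int]
    per_lambda_fraction: dict[float, float]
    n_valid: int


def sweep_and_ensemble(
    design: np.ndarray,
    target: np.ndarray,
    regulators: Sequence[str],
    cfg: TrainConfig,
    y_lag: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> SweepResult:
    """Fit across the lambda grid and ensemble the valid settings.

    A regulator's score is the mean over valid lambdas of its full
    first-layer group norm.  Its reported lag is the dominant lag: the lag
    whose weight block carries the largest mean norm across valid fits.
    Averaging the block-norm profile before reading off the lag suppresses
    small stray weights at neighbouring lags that spatially smooth
    expression induces in any single fit.
    """
    grid = cfg.grid()
    base_seed = cfg.seed if seed is None else seed
    fracs: dict[float, float] = {}
    valid_models: list[GrangerModel] = []
    for i, lam in enumerate(grid):
        model, diag = fit_single_lambda(
            design, target, cfg, lam, y_lag=y_lag,
            seed=int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31)),
        )
        fracs[float(lam)] = diag.nonzero_fraction
        if lambda_validity(model, cfg.validity_band):
            valid_models.append(model)
    if not valid_models:
        detail = ", ".join(f"{l:.4g}->{f:.2f}" for l, f in fracs.items())
        raise DataValidationError(
            "no valid lambda setting (nonzero fractions: "
            f"{detail}); sample from a broader range of lambda values"
        )
    scores: dict[str, float] = {}
    lags: dict[str, int] = {}
    for r, gene in enumerate(regulators):
        score = float(np.mean([m.group_norm(r) for m in valid_models]))
        block_profile = np.mean(
            [np.linalg.norm(m.W1[:, r, :], axis=1) for m in valid_models], axis=0
        )
        if score <= ZERO_TOL:
            scores[gene], lags[gene] = 0.0, 0
        else:
            scores[gene] = score
            lags[gene] = int(np.argmax(block_profile)) + 1
    return SweepResult(
        scores=scores, lags=lags, per_lambda_fraction=fracs,
        n_valid=len(valid_models),
    )


def run_glacier(
    dataset: SpatialExpressionDataset,
    pairs: CandidatePairList,
    field: IsodepthField,
    cfg: TrainConfig,
    direction: str = "forward",
    context: str = "",
    diagnostics: Optional[dict] = None,
) -> InteractionTable:
    """End-to-end inference: normalize, orient the spatial DAG, aggregate
    ancestors, and score every candidate pair.

    ``direction="backward"`` inverts the isodepth (reversing every DAG edge)
    before inference; ``"both"`` concatenates forward and backward runs with
    direction labels.  If a dict is passed as ``diagnostics`` it is filled
    with per-target sweep summaries (per-lambda nonzero fractions, number of
    valid settings).
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "both":
        fwd = run_glacier(dataset, pairs, field, cfg, "forward", context, diagnostics)
        bwd = run_glacier(dataset, pairs, field, cfg, "backward", context, diagnostics)
        return fwd.concat(bwd)

    pairs = pairs.resolve(dataset)
    if len(pairs) == 0:
        return InteractionTable()
    norm = normalize_expression(dataset, cfg.normalization)
    fld = invert_isodepth(field) if direction == "backward" else field
    knn = build_knn_graph(dataset.coords, cfg.k_neighbors)
    dag = orient_edges(knn, fld, k=cfg.k_neighbors)
    ops = build_lag_operators(dag, cfg.max_lag)
    logger.info(
        "%s run: %d cells, %d edges, %d candidate pairs",
        direction, dataset.n_cells, dag.n_edges, len(pairs),
    )

    pair_type = {(p.regulator, p.target): p.pair_type for p in pairs}
    dir_idx = 0 if direction == "forward" else 1
    rows = []
    for t_idx, target_gene in enumerate(pairs.targets):
        regs = pairs.regulators_of(target_gene)
        design = assemble_design(norm, regs, ops)
        y = norm.column(target_gene)
        y_lag = aggregate_self_lags(y, ops) if cfg.include_self_lags else None
        seed = int(
            np.random.SeedSequence([cfg.seed, dir_idx, t_idx]).generate_state(1)[0]
            % (2**31)
        )
        try:
            res = sweep_and_ensemble(design, y, regs, cfg, y_lag=y_lag, seed=seed)
        except DataValidationError as err:
            # No lambda in the grid gives a partially sparse model for this
            # target; every weight survives or dies together, so there is no
            # evidence of a *selective* regulator set.  Report zero scores
            # rather than aborting the remaining targets.
            logger.warning("target %s: %s; reporting zero scores", target_gene, err)
            res = SweepResult(
                scores={g: 0.0 for g in regs},
                lags={g: 0 for g in regs},
                per_lambda_fraction={},
                n_valid=0,
            )
        if diagnostics is not None:
            diagnostics[f"{direction}:{target_gene}"] = {
                "n_valid": res.n_valid,
                "per_lambda_nonzero_fraction": res.per_lambda_fraction,
            }
        for g in regs:
            rows.append(
                {
                    "regulator": g,
                    "target": target_gene,
                    "pair_type": pair_type[(g, target_gene)],
                    "direction": direction,
                    "score": res.scores[g],
                    "lag": res.lags[g],
                    "context": context,
                }
            )
    return InteractionTable(pd.DataFrame(rows)).sorted()


def stratified_partition(
    dataset: SpatialExpressionDataset,
    n_parts: int = 3,
    seed: int = 0,
) -> list[SpatialExpressionDataset]:
    """Split cells into ``n_parts`` disjoint subsets preserving the cell-type
    distribution: within each label class, shuffled cells are dealt
    round-robin, so per-class counts across parts differ by at most one."""
    if dataset.cell_labels is None:
        raise DataValidationError("stratified partition requires cell labels")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in range(n_parts)]
    for lab in np.unique(dataset.cell_labels):
        idx = np.flatnonzero(dataset.cell_labels == lab)
        if idx.size < n_parts:
            raise DataValidationError(
                f"class {lab!r} has {idx.size} cells, fewer than {n_parts} parts"
            )
        idx = rng.permutation(idx)
        for i, cell in enumerate(idx):
            parts[i % n_parts].append(int(cell))
    return [dataset.subset_cells(np.sort(p)) for p in parts]


@dataclass
class VARResult:
    causal: bool
    beta: np.ndarray
    alpha: np.ndarray
    f_stat: float
    p_value: float


def var_granger_oracle(
    x: np.ndarray, y: np.ndarray, max_lag: int, alpha_level: float = 0.05
) -> VARResult:
    """Classical linear Granger F-test on a pair of time series.

    OLS of the full model (own lags plus x lags) against the reduced model
    (own lags only); the null that every x coefficient is zero is rejected
    with an F-test.  Used as the brute-force oracle for the path-graph limit
    of the spatial method.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    T = y.size
    L = max_lag
    if T <= 2 * L + 2:
        raise DataValidationError(f"series too short (T={T}) for {L} lags")
    Y = y[L:]
    ylags = np.column_stack([y[L - l:T - l] for l in range(1, L + 1)])
    xlags = np.column_stack([x[L - l:T - l] for l in range(1, L + 1)])
    ones = np.ones((T - L, 1))
    full = np.hstack([ones, ylags, xlags])
    red = np.hstack([ones, ylags])
    beta_full, *_ = np.linalg.lstsq(full, Y, rcond=None)
    beta_red, *_ = np.linalg.lstsq(red, Y, rcond=None)
    rss_full = float(((Y - full @ beta_full) ** 2).sum())
    rss_red = float(((Y - red @ beta_red) ** 2).sum())
    dof = T - L - full.shape[1]
    f_stat = ((rss_red - rss_full) / L) / (rss_full / dof)
    p = float(stats.f.sf(f_stat, L, dof))
    return VARResult(
        causal=p < alpha_level,
        beta=beta_full[1 + L:],
        alpha=beta_full[1:1 + L],
        f_stat=float(f_stat),
        p_value=p,
    )
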