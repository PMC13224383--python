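"""Synthetic spatial transcriptomics with known ground truth.

Generates UMI-sparse Poisson counts whose per-gene log-rates are piecewise
linear in a smooth planted isodepth field, with optional regulator->target
effects propagating along the isodepth-oriented spatial DAG at known lags.
Every pipeline stage (isodepth recovery, DAG orientation, lag aggregation,
Granger scoring) can therefore be checked against the generating truth.

Per-cell UMI totals are drawn log-normal around 500, mimicking the sparse
bead-level coverage of Slide-SeqV2-class technologies at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .data import CandidatePair, CandidatePairList, SpatialExpressionDataset
from .dag import build_knn_graph, build_lag_operators, orient_edges, reverse_dag
from .isodepth import IsodepthField

RATE_CAP = 1e7


@dataclass(frozen=True)
class PlantedPair:
    """One planted causal interaction: the target's log-rate gains
    ``beta * (lag-step ancestor-averaged regulator expression)``."""

    regulator: str
    target: str
    lag: int
    beta: float
    direction: str = "forward"


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the method must recover."""

    true_isodepth: np.ndarray = None  # type: ignore[assignment]
    planted_pairs: list[PlantedPair] = dc_field(default_factory=list)
    noise_sd: float = 0.1
    umi_totals: Optional[np.ndarray] = None
    n_pieces: int = 1
    breakpoints: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    trend_scale: float = 0.8
    base_log_rate: Optional[float] = None
    intercept_sd: float = 0.3
    knn_k: int = 7
    normalized_propagation: bool = True
    true_dag_edges: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for p in self.planted_pairs:
            if not np.isfinite(p.beta):
                raise ValueError("planted effect size must be finite")


def make_spatial_field(
    n_cells: int,
    layout: str = "grid",
    seed: int = 0,
    extent: tuple[float, float] = (400.0, 200.0),
    n_layers: int = 1,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell coordinates plus a planted isodepth.

    Layouts: ``grid`` (regular lattice), ``uniform_random`` (uniform in a
    rectangle), ``layered_strip`` (uniform, with layer breakpoints at even
    quantiles of the isodepth).  The isodepth is a smooth monotone function
    of one coordinate axis, scaled to span the coordinate extent.

    Returns ``(coords, true_isodepth, breakpoints)``.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)
    W, H = extent
    if layout == "grid":
        nx = int(np.ceil(np.sqrt(n_cells * W / H)))
        ny = int(np.ceil(n_cells / nx))
        xs, ys = np.meshgrid(np.linspace(0, W, nx), np.linspace(0, H, ny))
        coords = np.column_stack([xs.ravel(), ys.ravel()])[:n_cells]
    elif layout in ("uniform_random", "layered_strip"):
        coords = rng.uniform([0, 0], [W, H], size=(n_cells, 2))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    a = coords[:, axis]
    span = a.max() - a.min()
    # smooth strictly monotone map of the chosen axis, rescaled to its extent
    u = (a - a.min()) / max(span, 1e-12)
    d = u + 0.15 * np.sin(np.pi * u) * u * (1 - u)
    d = span * (d - d.min()) / max(d.max() - d.min(), 1e-12)
    if n_layers > 1:
        qs = np.linspace(0, 1, n_layers + 1)[1:-1]
        breakpoints = np.quantile(d, qs)
    else:
        breakpoints = np.empty(0)
    return coords, d, breakpoints


def _piecewise_log_rates(
    d: np.ndarray, truth: SyntheticTruth, G: int, rng: np.random.Generator
) -> np.ndarray:
    """(N, G) baseline log-rates, piecewise linear in the true isodepth."""
    u = (d - d.min()) / max(d.max() - d.min(), 1e-12)
    if truth.n_pieces > 1:
        if truth.breakpoints.size:
            bps = (truth.breakpoints - d.min()) / max(d.max() - d.min(), 1e-12)
        else:
            bps = np.quantile(u, np.linspace(0, 1, truth.n_pieces + 1)[1:-1])
    else:
        bps = np.empty(0)
    base = truth.base_log_rate
    if base is None:
        base = float(np.log(0.5 / G))
    intercepts = rng.normal(base, truth.intercept_sd, G)
    slopes = rng.normal(0.0, truth.trend_scale, G)
    F = np.outer(u, slopes)
    for b in bps:
        F += np.outer(np.maximum(u - b, 0.0), rng.normal(0.0, truth.trend_scale, G))
    # centre each gene's trend so the intercept, not the slope, sets its level
    return F - F.mean(axis=0, keepdims=True) + intercepts[None, :]


def simulate_expression(
    coords: np.ndarray,
    true_isodepth: np.ndarray,
    truth: SyntheticTruth,
    G: int,
    seed: int = 0,
    gene_names: Optional[list[str]] = None,
) -> SpatialExpressionDataset:
    """Draw counts ``c_ig ~ Pois(U_i exp(f_g(d_i) + eps))`` with planted
    causal propagation along the true DAG.

    Planted pairs are applied after the baseline draw: the regulator's
    z-scored log1p-CPM expression is aggregated from lag-step ancestors with
    the same row-normalized operators used at inference time (an
    unnormalized-sum mode exists to probe generator/model mismatch), added to
    the target's log-rate with weight beta, and the target column redrawn.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    d = np.asarray(true_isodepth, float)
    N = coords.shape[0]
    if gene_names is None:
        gene_names = [f"g{i:03d}" for i in range(G)]
    if truth.umi_totals is not None:
        U = np.asarray(truth.umi_totals, float)
    else:
        U = np.maximum(np.round(rng.lognormal(np.log(500.0), 0.35, N)), 50.0)
    truth.true_isodepth = d

    F = _piecewise_log_rates(d, truth, G, rng)
    eps = rng.normal(0.0, truth.noise_sd, (N, G)) if truth.noise_sd > 0 else 0.0
    rates = U[:, None] * np.exp(F + eps)
    if rates.max() > RATE_CAP:
        raise ValueError("expression rates overflow; reduce effect/trend sizes")
    counts = rng.poisson(rates).astype(np.int64)

    if truth.planted_pairs:
        field = IsodepthField(values=d)
        knn = build_knn_graph(coords, truth.knn_k)
        dag_f = orient_edges(knn, field, k=truth.knn_k)
        truth.true_dag_edges = dag_f.edges
        max_lag = max(p.lag for p in truth.planted_pairs)
        ops = {
            "forward": build_lag_operators(dag_f, max_lag),
            "backward": build_lag_operators(reverse_dag(dag_f), max_lag),
        }
        name_to_idx = {g: i for i, g in enumerate(gene_names)}
        for p in truth.planted_pairs:
            r, t = name_to_idx[p.regulator], name_to_idx[p.target]
            xr = np.log1p(1e4 * counts[:, r] / U)
            sd = xr.std()
            z = (xr - xr.mean()) / (sd if sd > 1e-12 else 1.0)
            op = ops[p.direction].ops[p.lag - 1]
            if not truth.normalized_propagation:
                op = (op != 0).astype(float)  # raw walk-count sums
            delta = np.asarray(op @ z).ravel() * p.beta
            col = F[:, t] + delta
            e = eps[:, t] if np.ndim(eps) else 0.0
            new_rates = U * np.exp(col + e)
            if new_rates.max() > RATE_CAP:
                raise ValueError(
                    f"planted effect beta={p.beta} overflows expression rates"
                )
            counts[:, t] = rng.poisson(new_rates)
            F[:, t] = col
    else:
        field = IsodepthField(values=d)
        knn = build_knn_graph(coords, truth.knn_k)
        truth.true_dag_edges = orient_edges(knn, field, k=truth.knn_k).edges

    # U is the depth scale of the Poisson model; the realized row sum can
    # exceed it since only the simulated gene panel is emitted.
    return SpatialExpressionDataset(
        counts=counts, coords=coords, gene_names=gene_names,
        umi_totals=np.maximum(U, counts.sum(axis=1)),
    )


_SUITES = {
    "easy": dict(n_cells=500, n_genes=20, n_true=5, n_candidates=40, beta=1.2),
    "hard": dict(n_cells=500, n_genes=30, n_true=5, n_candidates=80, beta=0.4),
    "null": dict(n_cells=500, n_genes=20, n_true=0, n_candidates=40, beta=0.0),
}


def benchmark_suite(
    name: str, seed: int = 0
) -> tuple[SpatialExpressionDataset, CandidatePairList, SyntheticTruth]:
    """Named ground-truth benchmarks.

    ``easy``: 500 cells, 20 genes, 5 strongly planted pairs among 40
    candidates.  ``hard``: weaker effects and more decoys.  ``null``: no
    planted pairs at all (every candidate is a decoy).
    """
    if name not in _SUITES:
        raise ValueError(f"unknown suite {name!r}; choose from {sorted(_SUITES)}")
    p = _SUITES[name]
    rng = np.random.default_rng([seed, 987_001])
    G = p["n_genes"]
    genes = [f"g{i:03d}" for i in range(G)]
    regs = genes[: G // 2]
    targets = genes[G // 2:]

    lags = [1, 2, 3]
    true_pairs = [
        PlantedPair(regs[i], targets[i], lag=lags[i % 3], beta=p["beta"])
        for i in range(p["n_true"])
    ]
    true_keys = {(tp.regulator, tp.target) for tp in true_pairs}
    all_combos = [(r, t) for r in regs for t in targets if (r, t) not in true_keys]
    n_decoys = p["n_candidates"] - p["n_true"]
    decoy_idx = rng.choice(len(all_combos), size=n_decoys, replace=False)
    candidates = [CandidatePair(r, t) for r, t in true_keys] + [
        CandidatePair(*all_combos[i]) for i in sorted(decoy_idx)
    ]

    coords, d, bps = make_spatial_field(
        p["n_cells"], layout="uniform_random", seed=seed, n_layers=3
    )
    truth = SyntheticTruth(
        planted_pairs=true_pairs,
        n_pieces=3,
        breakpoints=bps,
        trend_scale=0.5,
        noise_sd=0.1,
    )
    dataset = simulate_expression(coords, d, truth, G, seed=seed, gene_names=genes)
    return dataset, CandidatePairList(candidates), truth
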