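"""Isodepth: a learned scalar spatial potential per cell.

The isodepth ``d(x, y)`` is a continuously differentiable scalar field over
the tissue whose level sets track the direction of maximum spatial variation
in gene expression (layer depth in layered tissues).  Expression is modelled
as a composition ``f(x, y) = h(d(x, y))`` where ``h`` is a per-feature
piecewise-linear function of the single coordinate ``d`` with shared
breakpoints.  Fitting maximizes the data likelihood jointly over the field
and the 1-D expression model.

The field is parameterized as a linear map of the (centred) coordinates plus
a small tanh-MLP residual, so it is smooth by construction and exactly
invariant to translating all coordinates.  The 1-D model ``h`` uses a hinge
basis ``[1, d, (d - b_1)_+, ..., (d - b_{P-1})_+]`` which is continuous at
every breakpoint by construction.  Isodepth is identifiable only up to a
monotone transform; after fitting it is affinely rescaled so its range equals
the spatial extent of the tissue (bounding-box diagonal), which makes
micrometre-scale boundary widths meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from ._optim import Adam
from .data import DataValidationError, SpatialExpressionDataset, normalize_expression

logger = logging.getLogger("glacier")


@dataclass
class IsodepthField:
    """Per-cell scalar potential with layer structure.

    ``layer_labels[i] = p`` iff ``b_p <= values[i] < b_{p+1}`` with sentinel
    +/- infinity ends (half-open intervals).
    """

    values: np.ndarray
    breakpoints: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    layer_labels: np.ndarray = None  # type: ignore[assignment]
    inverted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise DataValidationError("isodepth values must be finite")
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.breakpoints.size and (np.diff(self.breakpoints) <= 0).any():
            raise DataValidationError("breakpoints must be strictly increasing")
        if self.layer_labels is None:
            self.layer_labels = assign_layers(self.values, self.breakpoints)

    @property
    def n_layers(self) -> int:
        return self.breakpoints.size + 1


def assign_layers(values: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    """Half-open layer assignment: cell in layer p iff b_p <= d < b_{p+1}."""
    return np.searchsorted(np.asarray(breakpoints, float), values, side="right")


def attach_isodepth(
    dataset: SpatialExpressionDataset,
    values: np.ndarray,
    breakpoints: np.ndarray = (),
) -> IsodepthField:
    """Wrap a precomputed isodepth vector (e.g. an external fit) as a field."""
    values = np.asarray(values, dtype=float)
    if values.shape != (dataset.n_cells,):
        raise DataValidationError(
            f"isodepth has length {values.shape}, dataset has {dataset.n_cells} cells"
        )
    return IsodepthField(values=values, breakpoints=np.asarray(breakpoints, float))


def invert_isodepth(field: IsodepthField) -> IsodepthField:
    """Reverse the isodepth ordering: d'_i = max_j(d_j) - d_i.

    Layer labels are recomputed against the transformed breakpoints, so the
    first layer under d becomes the last under d'.
    """
    m = field.values.max()
    new_values = m - field.values
    # b' = m - b, reversed to stay increasing; layers use half-open intervals
    # on the new axis.
    new_bp = np.sort(m - field.breakpoints) if field.breakpoints.size else np.empty(0)
    return IsodepthField(
        values=new_values, breakpoints=new_bp, inverted=not field.inverted
    )


def select_layer(
    dataset: SpatialExpressionDataset, field: IsodepthField, layer_index: int
) -> SpatialExpressionDataset:
    """Subset cells carrying the given layer label."""
    if not 0 <= layer_index < field.n_layers:
        raise IndexError(
            f"layer {layer_index} out of range for {field.n_layers} layers"
        )
    idx = np.flatnonzero(field.layer_labels == layer_index)
    if idx.size == 0:
        raise DataValidationError(f"layer {layer_index} contains no cells")
    return dataset.subset_cells(idx)


def select_boundary(
    dataset: SpatialExpressionDataset,
    field: IsodepthField,
    boundary_value: Optional[float] = None,
    width: float = 50.0,
) -> SpatialExpressionDataset:
    """Subset cells within ``width`` isodepth units of a layer boundary.

    ``boundary_value`` defaults to the first fitted breakpoint.  With the
    post-fit rescaling of isodepth to the tissue's spatial extent, widths are
    on the micrometre scale of the coordinates (e.g. 50 um).
    """
    if width < 0:
        raise ValueError("width must be nonnegative")
    if boundary_value is None:
        if not field.breakpoints.size:
            raise ValueError("no breakpoints to default the boundary to")
        boundary_value = float(field.breakpoints[0])
    idx = np.flatnonzero(np.abs(field.values - boundary_value) <= width)
    if idx.size == 0:
        raise DataValidationError(
            f"no cells within {width} of boundary {boundary_value}"
        )
    return dataset.subset_cells(idx)


@dataclass
class PiecewiseExpression:
    """The fitted 1-D expression model h, one piecewise-linear curve per feature.

    ``intercept`` and ``slope`` give the first piece; ``hinge_coefs[p]`` adds
    to the slope past breakpoint p (cumulative form), so continuity at every
    breakpoint holds exactly.  Features are reduced components under the
    Gaussian-on-reduced likelihood, or genes under the Poisson likelihood.
    """

    breakpoints: np.ndarray
    intercept: np.ndarray  # (K,)
    slope: np.ndarray  # (K,)
    hinge_coefs: np.ndarray  # (P-1, K)
    feature_names: list[str]

    @property
    def n_pieces(self) -> int:
        return self.breakpoints.size + 1

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, float))
        out = self.intercept[None, :] + np.outer(d, self.slope)
        for p, b in enumerate(self.breakpoints):
            out += np.outer(np.maximum(d - b, 0.0), self.hinge_coefs[p])
        return out

    def slopes_per_piece(self) -> np.ndarray:
        """(P, K) slope of each feature on each piece (cumulative sums)."""
        return np.vstack([self.slope[None, :], self.hinge_coefs]).cumsum(axis=0)


@dataclass
class IsodepthFitConfig:
    """Settings for the isodepth fit.

    ``n_pieces`` is the number of linear pieces P of the 1-D model (P-1
    breakpoints).  ``reduction_dims`` is the number of expression principal
    components used under the Gaussian likelihood.  ``likelihood`` is
    ``gaussian_on_reduced`` (default: PCA of z-scored log1p-CPM, Gaussian
    error) or ``poisson`` (counts modelled as Pois(U_i exp h_g(d_i))).
    """

    n_pieces: int = 1
    reduction_dims: int = 5
    likelihood: str = "gaussian_on_reduced"
    seed: int = 0
    epochs: int = 800
    learning_rate: float = 0.01
    hidden_width: int = 16
    warmup_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.n_pieces < 1:
            raise ValueError("n_pieces must be >= 1")
        if self.likelihood not in ("gaussian_on_reduced", "poisson"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


def _hinge_basis(d: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(d), d]
    for b in breakpoints:
        cols.append(np.maximum(d - b, 0.0))
    return np.column_stack(cols)


def _hinge_basis_deriv(d: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    cols = [np.zeros_like(d), np.ones_like(d)]
    for b in breakpoints:
        cols.append((d > b).astype(float))
    return np.column_stack(cols)


class _FieldNet:
    """d(s) = s @ w + c + v . tanh(W2 tanh(W1 s + b1) + b2), s centred."""

    def __init__(self, rng: np.random.Generator, hidden: int, w_init: np.ndarray):
        self.w = w_init.astype(float).copy()
        self.c = np.zeros(1)
        s = 0.1
        self.W1 = rng.normal(0, s, (2, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0, s / np.sqrt(hidden), (hidden, hidden))
        self.b2 = np.zeros(hidden)
        self.v = rng.normal(0, s / np.sqrt(hidden), hidden)

    def params(self) -> list[np.ndarray]:
        return [self.w, self.c, self.W1, self.b1, self.W2, self.b2, self.v]

    def forward(self, s: np.ndarray):
        z1 = s @ self.W1 + self.b1
        a1 = np.tanh(z1)
        z2 = a1 @ self.W2 + self.b2
        a2 = np.tanh(z2)
        d = s @ self.w + self.c[0] + a2 @ self.v
        return d, (s, a1, a2)

    def backward(self, cache, g_d: np.ndarray) -> list[np.ndarray]:
        s, a1, a2 = cache
        dv = a2.T @ g_d
        da2 = np.outer(g_d, self.v) * (1 - a2 * a2)
        dW2 = a1.T @ da2
        db2 = da2.sum(axis=0)
        da1 = (da2 @ self.W2.T) * (1 - a1 * a1)
        dW1 = s.T @ da1
        db1 = da1.sum(axis=0)
        dw = s.T @ g_d
        dc = np.array([g_d.sum()])
        return [dw, dc, dW1, db1, dW2, db2, dv]


def _reduced_representation(
    dataset: SpatialExpressionDataset, dims: int, seed: int
) -> tuple[np.ndarray, list[str]]:
    from sklearn.decomposition import PCA

    norm = normalize_expression(dataset, "log_cpm_z")
    keep = [g not in norm.zero_variance_genes for g in norm.gene_names]
    vals = norm.values[:, np.asarray(keep)]
    if vals.shape[1] == 0:
        raise DataValidationError("all genes are constant; isodepth is undefined")
    dims = min(dims, vals.shape[1], vals.shape[0] - 1)
    pca = PCA(n_components=dims, random_state=seed, svd_solver="full")
    Y = pca.fit_transform(vals)
    Y = Y / Y.std(axis=0).clip(1e-12)
    return Y, [f"PC{i+1}" for i in range(dims)]


def fit_isodepth(
    dataset: SpatialExpressionDataset, cfg: IsodepthFitConfig
) -> tuple[IsodepthField, PiecewiseExpression]:
    """Jointly fit the smooth field d(x, y) and the piecewise-linear model h.

    Alternating scheme: the hinge-basis coefficients of h are refit in closed
    form (ordinary least squares on the reduced representation) while the
    field network takes Adam steps on the resulting squared-error loss.  A
    warm-up phase runs with a single piece; breakpoints are then initialized
    at quantiles of the current field and periodically refreshed.  Under the
    ``poisson`` likelihood the basis coefficients are updated by gradient
    steps on the Poisson deviance instead of OLS.

    Returns the fitted field (rescaled to the tissue's spatial extent, with
    layer labels from the fitted breakpoints) and the fitted h.
    """
    N = dataset.n_cells
    if N < 2 or np.unique(dataset.coords, axis=0).shape[0] < 2:
        raise DataValidationError("need at least 2 distinct spatial locations")
    if cfg.n_pieces > max(1, N // 10):
        raise DataValidationError(
            f"n_pieces={cfg.n_pieces} is too large for N={N} cells"
        )
    rng = np.random.default_rng(cfg.seed)

    coords = dataset.coords
    center = coords.mean(axis=0)
    scale = coords.std(axis=0).clip(1e-12).max()
    s = (coords - center) / scale

    if cfg.likelihood == "gaussian_on_reduced":
        Y, feat_names = _reduced_representation(dataset, cfg.reduction_dims, cfg.seed)
    else:
        norm = normalize_expression(dataset, "log_cpm_z")
        if len(norm.zero_variance_genes) == dataset.n_genes:
            raise DataValidationError("all genes are constant; isodepth is undefined")
        Y = None
        feat_names = list(dataset.gene_names)

    # Linear warm start: project the dominant expression direction onto the
    # coordinates so the field begins aligned with the main spatial trend.
    if cfg.likelihood == "gaussian_on_reduced":
        y0 = Y[:, 0]
    else:
        y0 = np.log1p(dataset.counts.sum(axis=1))
        if y0.std() < 1e-12:
            y0 = rng.normal(size=N)
    A = np.column_stack([s, np.ones(N)])
    coef, *_ = np.linalg.lstsq(A, (y0 - y0.mean()) / y0.std().clip(1e-12), rcond=None)
    net = _FieldNet(rng, cfg.hidden_width, w_init=coef[:2])

    opt = Adam(net.params(), lr=cfg.learning_rate)
    warmup = max(1, int(cfg.warmup_frac * cfg.epochs))
    freeze_at = int(0.8 * cfg.epochs)
    breakpoints = np.empty(0)

    if cfg.likelihood == "poisson":
        U = dataset.umi_totals
        C = dataset.counts.astype(float)
        B = None

    for epoch in range(cfg.epochs):
        d, cache = net.forward(s)
        if cfg.n_pieces > 1 and epoch >= warmup and (
            epoch == warmup or (epoch < freeze_at and epoch % 50 == 0)
        ):
            qs = np.linspace(0, 1, cfg.n_pieces + 1)[1:-1]
            breakpoints = np.unique(np.quantile(d, qs))
        Phi = _hinge_basis(d, breakpoints)
        dPhi = _hinge_basis_deriv(d, breakpoints)
        if cfg.likelihood == "gaussian_on_reduced":
            B, *_ = np.linalg.lstsq(Phi, Y, rcond=None)
            R = Phi @ B - Y  # (N, K)
            g_d = (2.0 / R.size) * np.einsum("nk,nj,jk->n", R, dPhi, B)
        else:
            if B is None or B.shape[0] != Phi.shape[1]:
                B = np.zeros((Phi.shape[1], C.shape[1]))
                B[0] = np.log(C.mean(axis=0).clip(1e-8) / U.mean())
            # one Newton-free gradient step on B per epoch
            F = np.clip(Phi @ B, -30, 10)
            Lam = U[:, None] * np.exp(F)
            G = Lam - C  # d(-loglik)/dF
            B -= 0.05 * (Phi.T @ G) / N
            F = np.clip(Phi @ B, -30, 10)
            Lam = U[:, None] * np.exp(F)
            G = Lam - C
            g_d = np.einsum("ng,nj,jg->n", G, dPhi, B) / (N * C.shape[1])
        grads = net.backward(cache, g_d)
        opt.step(grads)

    d, _ = net.forward(s)
    if cfg.likelihood == "gaussian_on_reduced":
        Phi = _hinge_basis(d, breakpoints)
        B, *_ = np.linalg.lstsq(Phi, Y, rcond=None)

    # Rescale d to the tissue's spatial extent (bounding-box diagonal) so
    # boundary widths are in coordinate units.
    span = float(np.linalg.norm(coords.max(axis=0) - coords.min(axis=0)))
    d_min, d_max = d.min(), d.max()
    if d_max - d_min < 1e-12:
        raise DataValidationError(
            "fitted isodepth is constant (no direction of expression variation)"
        )
    a = span / (d_max - d_min)
    d_scaled = (d - d_min) * a
    bp_scaled = (breakpoints - d_min) * a if breakpoints.size else np.empty(0)

    # Transform h to the rescaled axis: h(d) = h((d_scaled / a) + d_min).
    intercept = B[0] + d_min * B[1]
    slope = B[1] / a
    hinge = B[2:] / a if B.shape[0] > 2 else np.zeros((0, B.shape[1]))
    pw = PiecewiseExpression(
        breakpoints=bp_scaled,
        intercept=intercept,
        slope=slope,
        hinge_coefs=hinge,
        feature_names=feat_names,
    )
    field = IsodepthField(values=d_scaled, breakpoints=bp_scaled)
    logger.info(
        "isodepth fit: %d cells, %d pieces, range [0, %.1f]",
        N, cfg.n_pieces, d_scaled.max(),
    )
    return field, pw


def write_isodepth(field: IsodepthField, path) -> None:
    """Two-column TSV (cell_id, isodepth)."""
    import pandas as pd

    pd.DataFrame(
        {"cell_id": np.arange(field.values.size), "isodepth": field.values}
    ).to_csv(path, sep="\t", index=False)


def read_isodepth(path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path, sep="\t")["isodepth"].to_numpy(float)
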