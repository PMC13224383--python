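"""Core dataset containers and I/O for spatial transcriptomics.

The central object is :class:`SpatialExpressionDataset`: an ``N x G``
nonnegative integer UMI count matrix together with an ``N x 2`` matrix of
spatial coordinates (in micrometres, taken as-is from the source file with no
axis flipping).  Candidate regulator->target gene pairs (TF-target or
ligand-receptor, CellChatDB-style tables) are held in
:class:`CandidatePairList`, and the method's output in
:class:`InteractionTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("glacier")

PAIR_TYPES = ("tf_target", "ligand_receptor")

INTERACTION_COLUMNS = [
    "regulator",
    "target",
    "pair_type",
    "direction",
    "score",
    "lag",
    "context",
]


class DataValidationError(ValueError):
    """Raised when an input file or array violates a dataset invariant."""


@dataclass
class SpatialExpressionDataset:
    """UMI counts plus spatial coordinates for N cells and G genes.

    Parameters
    ----------
    counts
        ``(N, G)`` nonnegative integer-valued matrix of UMI counts.
    coords
        ``(N, 2)`` real matrix of spatial locations in micrometres.
    gene_names
        Length-``G`` unique gene identifiers.
    cell_labels
        Optional length-``N`` categorical labels (cell type or layer).
    umi_totals
        Optional length-``N`` positive totals ``U_i``; defaults to per-cell
        row sums of ``counts``.
    cell_ids
        Optional original indices, retained through subsetting.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    cell_labels: Optional[np.ndarray] = None
    umi_totals: Optional[np.ndarray] = None
    cell_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        _validate_counts(self.counts)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataValidationError(
                f"coords must be N x 2, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] != self.counts.shape[0]:
            raise DataValidationError(
                f"counts has {self.counts.shape[0]} cells but coords has "
                f"{self.coords.shape[0]} rows"
            )
        if len(self.gene_names) != self.counts.shape[1]:
            raise DataValidationError(
                f"{len(self.gene_names)} gene names for "
                f"{self.counts.shape[1]} count columns"
            )
        dupes = pd.Index(self.gene_names).duplicated()
        if dupes.any():
            bad = [g for g, d in zip(self.gene_names, dupes) if d]
            raise DataValidationError(f"duplicate gene names: {sorted(set(bad))}")
        if self.umi_totals is None:
            self.umi_totals = self.counts.sum(axis=1).astype(float)
        else:
            self.umi_totals = np.asarray(self.umi_totals, dtype=float)
            if self.umi_totals.shape != (self.n_cells,):
                raise DataValidationError("umi_totals length mismatch")
            if (self.umi_totals < self.counts.sum(axis=1) - 1e-9).any():
                raise DataValidationError(
                    "umi_totals smaller than per-cell count sums"
                )
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels)
            if self.cell_labels.shape != (self.n_cells,):
                raise DataValidationError("cell_labels length mismatch")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.n_cells)
        else:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in dataset") from None

    def subset_cells(self, idx: np.ndarray) -> "SpatialExpressionDataset":
        """Row subset preserving original indices in ``cell_ids``."""
        idx = np.asarray(idx)
        return SpatialExpressionDataset(
            counts=self.counts[idx],
            coords=self.coords[idx],
            gene_names=list(self.gene_names),
            cell_labels=None if self.cell_labels is None else self.cell_labels[idx],
            umi_totals=self.umi_totals[idx],
            cell_ids=self.cell_ids[idx],
        )


def _validate_counts(counts: np.ndarray) -> None:
    if counts.ndim != 2:
        raise DataValidationError(f"counts must be 2-D, got {counts.ndim}-D")
    neg = np.argwhere(counts < 0)
    if neg.size:
        i, j = neg[0]
        raise DataValidationError(
            f"negative count {counts[i, j]} at cell {i}, gene column {j}"
        )
    frac = np.argwhere(counts != np.floor(counts))
    if frac.size:
        i, j = frac[0]
        raise DataValidationError(
            f"non-integer count {counts[i, j]} at cell {i}, gene column {j}"
        )


@dataclass(frozen=True)
class CandidatePair:
    regulator: str
    target: str
    pair_type: str = "tf_target"


@dataclass
class CandidatePairList:
    """Candidate regulator->target pairs to be tested for Granger causality."""

    pairs: list[CandidatePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        out: list[CandidatePair] = []
        n_dup = 0
        for p in self.pairs:
            if p.pair_type not in PAIR_TYPES:
                raise DataValidationError(f"unknown pair type {p.pair_type!r}")
            key = (p.regulator, p.target, p.pair_type)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            out.append(p)
        if n_dup:
            logger.warning("dropped %d duplicate candidate pairs", n_dup)
        self.pairs = out

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def regulators(self) -> list[str]:
        return sorted({p.regulator for p in self.pairs})

    @property
    def targets(self) -> list[str]:
        return sorted({p.target for p in self.pairs})

    def regulators_of(self, target: str) -> list[str]:
        return sorted({p.regulator for p in self.pairs if p.target == target})

    def resolve(self, dataset: SpatialExpressionDataset) -> "CandidatePairList":
        """Drop pairs naming genes absent from *dataset* (count is logged)."""
        names = set(dataset.gene_names)
        kept = [p for p in self.pairs if p.regulator in names and p.target in names]
        n_dropped = len(self.pairs) - len(kept)
        if n_dropped:
            logger.warning(
                "dropped %d candidate pairs with unresolvable genes", n_dropped
            )
        if self.pairs and not kept:
            raise DataValidationError(
                "no candidate pair could be resolved against the dataset"
            )
        return CandidatePairList(kept)


@dataclass
class NormalizedExpression:
    """Per-gene scaled expression aligned row-for-row with its source dataset.

    With the default ``log_cpm_z`` scheme each gene column of ``values`` is the
    z-score over cells of ``log(1 + 1e4 * count / U_i)``; constant genes are
    kept as all-zero columns and listed in ``zero_variance_genes`` so candidate
    pair indices stay stable.
    """

    values: np.ndarray
    scheme: str
    gene_names: list[str]
    zero_variance_genes: list[str] = field(default_factory=list)

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_names.index(gene)]


def normalize_expression(
    dataset: SpatialExpressionDataset,
    scheme: str = "log_cpm_z",
    on_zero_umi: str = "drop",
) -> NormalizedExpression:
    """Normalize counts for the Granger stage.

    ``log_cpm_z``: per gene, z-score over cells of log1p CPM with scale factor
    1e4.  ``none`` passes raw counts through as floats.  Cells with zero total
    UMIs carry no signal and break CPM; they are dropped with a logged count by
    default (``on_zero_umi="raise"`` to opt into an error).
    """
    if scheme == "none":
        return NormalizedExpression(
            values=dataset.counts.astype(float),
            scheme="none",
            gene_names=list(dataset.gene_names),
        )
    if scheme != "log_cpm_z":
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    u = dataset.umi_totals
    zero = u <= 0
    if zero.any():
        if on_zero_umi == "raise":
            raise DataValidationError(
                f"{int(zero.sum())} cells have zero total UMIs"
            )
        logger.warning("dropping %d zero-UMI cells", int(zero.sum()))
        dataset = dataset.subset_cells(np.flatnonzero(~zero))
        u = dataset.umi_totals
    vals = np.log1p(1e4 * dataset.counts / u[:, None])
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    constant = sd < 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    z = (vals - mu) / sd_safe
    z[:, constant] = 0.0
    zv = [g for g, c in zip(dataset.gene_names, constant) if c]
    if zv:
        logger.warning("%d zero-variance genes kept as all-zero columns", len(zv))
    return NormalizedExpression(
        values=z,
        scheme="log_cpm_z",
        gene_names=list(dataset.gene_names),
        zero_variance_genes=zv,
    )


@dataclass
class InteractionTable:
    """Scored (regulator, target) pairs: the method's output.

    One row per (regulator, target, direction, context); ``score`` is the
    ensembled first-layer group norm (nonnegative, zero iff no weight
    survived, in which case ``lag`` is 0) and ``lag`` is the estimated graph
    lag of the interaction.
    """

    rows: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rows is None:
            self.rows = pd.DataFrame(columns=INTERACTION_COLUMNS)
        missing = [c for c in INTERACTION_COLUMNS if c not in self.rows.columns]
        if missing:
            raise DataValidationError(f"interaction table missing {missing}")
        self.rows = self.rows[INTERACTION_COLUMNS].reset_index(drop=True)
        if len(self.rows):
            if (self.rows["score"] < 0).any():
                raise DataValidationError("negative interaction score")
            zero_lag = self.rows["lag"] == 0
            zero_score = self.rows["score"] == 0
            if (zero_lag != zero_score).any():
                raise DataValidationError("lag is 0 iff score is 0 violated")
            key = self.rows[["regulator", "target", "direction", "context"]]
            if key.duplicated().any():
                raise DataValidationError(
                    "duplicate (regulator, target, direction, context) rows"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def sorted(self) -> "InteractionTable":
        """Bit-stable ordering: score descending, then lexicographic."""
        df = self.rows.sort_values(
            by=["score", "regulator", "target", "direction", "context"],
            ascending=[False, True, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        return InteractionTable(df)

    def concat(self, other: "InteractionTable") -> "InteractionTable":
        return InteractionTable(
            pd.concat([self.rows, other.rows], ignore_index=True)
        )


def write_interactions(table: InteractionTable, path) -> None:
    """Write an interaction table as TSV in bit-stable order."""
    df = table.sorted().rows.copy()
    df["score"] = df["score"].map(lambda s: format(float(s), ".10g"))
    df.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype={"context": str})
    if len(df) == 0:
        return InteractionTable()
    df["context"] = df["context"].fillna("")
    df["score"] = df["score"].astype(float)
    df["lag"] = df["lag"].astype(int)
    return InteractionTable(df)


def read_pairs(path, default_type: str = "tf_target") -> CandidatePairList:
    """Read a two- or three-column delimited (regulator, target[, type]) table.

    A header row is detected by the literal column name ``regulator``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise DataValidationError(f"empty pair file {path}")
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.empty:
        raise DataValidationError(f"empty pair file {path}")
    if str(df.iloc[0, 0]).lower() == "regulator":
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise DataValidationError(f"pair file {path} has a header but no rows")
    if df.shape[1] < 2:
        raise DataValidationError("pair table needs at least 2 columns")
    pairs = []
    for _, row in df.iterrows():
        ptype = row.iloc[2] if df.shape[1] > 2 and pd.notna(row.iloc[2]) else default_type
        pairs.append(CandidatePair(str(row.iloc[0]), str(row.iloc[1]), str(ptype)))
    return CandidatePairList(pairs)


def write_pairs(pairs: CandidatePairList, path) -> None:
    df = pd.DataFrame(
        [(p.regulator, p.target, p.pair_type) for p in pairs],
        columns=["regulator", "target", "pair_type"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path, fmt: Optional[str] = None) -> SpatialExpressionDataset:
    """Read a dataset from one of the supported on-disk layouts.

    ``mtx_dir``
        A directory with ``matrix.mtx`` (cells x genes, Matrix Market 1-based),
        ``features.tsv`` (gene names), ``barcodes.tsv`` (cell ids) and
        ``coords.tsv`` (x, y per cell).
    ``csv``
        A dense counts CSV (cells x genes, gene-name header, first column cell
        id) with a ``<stem>.coords.csv`` sidecar.
    ``h5``
        An AnnData ``.h5ad`` with raw counts in ``.X`` and coordinates under
        ``obsm["spatial"]``.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif path.suffix in {".h5", ".h5ad"}:
            fmt = "h5"
        else:
            fmt = "csv"
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "h5":
        return _read_h5(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_mtx_dir(path: Path) -> SpatialExpressionDataset:
    from scipy.io import mmread

    mat = mmread(path / "matrix.mtx")
    counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    coords = pd.read_csv(path / "coords.tsv", sep="\t", header=None).to_numpy(float)
    if counts.shape[0] != len(barcodes):
        raise DataValidationError(
            f"matrix has {counts.shape[0]} rows but {len(barcodes)} barcodes"
        )
    return SpatialExpressionDataset(counts=counts, coords=coords, gene_names=genes)


def _read_csv(path: Path) -> SpatialExpressionDataset:
    df = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix("").with_suffix(".coords.csv")
    if not sidecar.exists():
        sidecar = path.parent / (path.stem + ".coords.csv")
    coords = pd.read_csv(sidecar, index_col=0).to_numpy(float)
    return SpatialExpressionDataset(
        counts=df.to_numpy(), coords=coords, gene_names=list(df.columns)
    )


def _read_h5(path: Path) -> SpatialExpressionDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    counts = np.asarray(X.todense() if hasattr(X, "todense") else X)
    if "spatial" not in adata.obsm:
        raise DataValidationError('h5ad file lacks obsm["spatial"] coordinates')
    labels = None
    if "cell_type" in adata.obs:
        labels = adata.obs["cell_type"].to_numpy()
    return SpatialExpressionDataset(
        counts=counts,
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        gene_names=list(adata.var_names),
        cell_labels=labels,
    )


def write_dataset(dataset: SpatialExpressionDataset, path, fmt: str = "csv") -> None:
    """Write a dataset as dense CSV (+ coords sidecar) or an MTX directory."""
    path = Path(path)
    if fmt == "csv":
        df = pd.DataFrame(dataset.counts, columns=dataset.gene_names)
        df.index.name = "cell"
        df.to_csv(path)
        cdf = pd.DataFrame(dataset.coords, columns=["x", "y"])
        cdf.index.name = "cell"
        cdf.to_csv(path.parent / (path.stem + ".coords.csv"))
    elif fmt == "mtx_dir":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), csr_matrix(dataset.counts))
        pd.Series(dataset.gene_names).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        pd.Series([f"cell_{i}" for i in range(dataset.n_cells)]).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(dataset.coords).to_csv(
            path / "coords.tsv", sep="\t", index=False, header=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
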