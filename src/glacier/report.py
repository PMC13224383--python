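"""Post-hoc summaries of an interaction table.

Lag estimates proxy the spatial range of a regulator: bigger lags mean the
regulator's influence reaches further across the tissue graph.  Summaries
here are pure functions of the interaction table, so recomputing them from a
written TSV reproduces the in-memory results exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .data import InteractionTable


def rank_frequent_targets(
    table: InteractionTable, min_score: float = 0.0
) -> list[tuple[str, int]]:
    """Targets ranked by how many distinct regulators hit them.

    Counts distinct regulators with score >= min_score per target, sorted by
    count descending then target name.
    """
    df = table.rows
    df = df[df["score"] >= min_score]
    if df.empty:
        return []
    counts = (
        df.groupby("target")["regulator"].nunique().reset_index(name="n")
    )
    counts = counts.sort_values(["n", "target"], ascending=[False, True])
    return [(r.target, int(r.n)) for r in counts.itertuples()]


@dataclass
class LagSummary:
    """Per-regulator lag distributions within one context."""

    context: str
    lags: dict[str, list[int]] = dc_field(default_factory=dict)
    mean_lag: dict[str, float] = dc_field(default_factory=dict)
    weighted_mean_lag: dict[str, float] = dc_field(default_factory=dict)
    longest_range: list[str] = dc_field(default_factory=list)
    shortest_range: list[str] = dc_field(default_factory=list)


def summarize_lags(table: InteractionTable, context: str = "") -> LagSummary:
    """Per-regulator lag lists over detected (score > 0) interactions in a
    context, with score-weighted mean lags and extremal-range flags."""
    df = table.rows
    df = df[(df["context"] == context) & (df["score"] > 0)]
    if df.empty:
        raise KeyError(f"no detected interactions for context {context!r}")
    out = LagSummary(context=context)
    for reg, grp in df.groupby("regulator"):
        lags = grp["lag"].astype(int).tolist()
        w = grp["score"].to_numpy(float)
        out.lags[reg] = lags
        out.mean_lag[reg] = float(np.mean(lags))
        out.weighted_mean_lag[reg] = float(np.average(lags, weights=w))
    if len(out.mean_lag) > 1:
        mx = max(out.mean_lag.values())
        mn = min(out.mean_lag.values())
        out.longest_range = sorted(r for r, m in out.mean_lag.items() if m == mx)
        out.shortest_range = sorted(r for r, m in out.mean_lag.items() if m == mn)
    return out


def lag_histogram(table: InteractionTable, context: str = "") -> pd.Series:
    """Counts of detected interactions per lag (bimodality is summarized
    visually only; no formal test is claimed)."""
    df = table.rows
    df = df[(df["context"] == context) & (df["score"] > 0)]
    return df["lag"].astype(int).value_counts().sort_index()
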