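"""Group-difference significance analysis of the performance metrics.

Two layouts mirror the study's printed tables: within each skill group, each
metric is compared across the two vascular-difficulty (VD) levels; within
each VD level, the expert and novice groups are compared.  Cells are
two-sided t-test p-values, flagged significant at alpha = 0.05.  The Welch
(unequal-variance) form is the default; the pooled-variance form and an
optional Benjamini-Hochberg correction are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import TABLE_ROW_ORDER

__all__ = ["SignificanceTable", "two_sample_t", "build_significance_tables"]


def two_sample_t(a, b, variant: str = "welch") -> float:
    """Two-sided two-sample t-test p-value.

    ``variant="welch"`` (default) uses the unequal-variance form,
    ``variant="pooled"`` the classic pooled-variance form.  Two degenerate
    zero-variance samples with equal means give p = 1.0 (no evidence of a
    difference); with different means, p = 0.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.pvalue)


@dataclass(eq=False)
class SignificanceTable:
    """p-values (rows = metrics, columns = comparisons) plus significance flags."""

    p_values: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values < self.alpha

    def to_json_dict(self) -> dict:
        out = {}
        for metric in self.p_values.index:
            out[metric] = {}
            for col in self.p_values.columns:
                p = self.p_values.loc[metric, col]
                out[metric][col] = {
                    "p": None if pd.isna(p) else float(p),
                    "significant": bool(p < self.alpha) if not pd.isna(p) else None,
                }
        return {"alpha": self.alpha, "cells": out}


def _bh_adjust(frame: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment over all finite cells of a table."""
    flat = frame.to_numpy().ravel()
    mask = np.isfinite(flat)
    p = flat[mask]
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = prev
    out = flat.copy()
    out[mask] = adj
    return pd.DataFrame(out.reshape(frame.shape), index=frame.index,
                        columns=frame.columns)


def build_significance_tables(
    metric_table: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "welch",
    bh_correct: bool = False,
):
    """Build the within-group and between-group significance tables.

    ``metric_table`` holds one row per trial with the metric columns of
    :data:`~wireskill.metrics.TABLE_ROW_ORDER` plus ``group`` (expert/novice)
    and ``vascular_difficulty`` (1/2).  Returns
    ``(within_group, between_group)``: within-group compares the two VD
    levels for each metric inside each skill group; between-group compares
    the two skill groups for each metric inside each VD level.  Strata with
    fewer than two trials give NaN cells (recorded, not raised).
    """
    df = metric_table
    groups = sorted(df["group"].unique())
    levels = sorted(df["vascular_difficulty"].unique())

    within = pd.DataFrame(index=list(TABLE_ROW_ORDER), columns=groups, dtype=float)
    for g in groups:
        sub = df[df["group"] == g]
        lo = sub[sub["vascular_difficulty"] == levels[0]]
        hi = sub[sub["vascular_difficulty"] == levels[-1]] if len(levels) > 1 else sub.iloc[0:0]
        for metric in TABLE_ROW_ORDER:
            if len(levels) < 2 or len(lo) < 2 or len(hi) < 2:
                within.loc[metric, g] = np.nan
            else:
                within.loc[metric, g] = two_sample_t(lo[metric], hi[metric], variant)

    cols = [f"vd{lvl}" for lvl in levels]
    between = pd.DataFrame(index=list(TABLE_ROW_ORDER), columns=cols, dtype=float)
    for lvl, col in zip(levels, cols):
        sub = df[df["vascular_difficulty"] == lvl]
        a = sub[sub["group"] == groups[0]]
        b = sub[sub["group"] == groups[-1]] if len(groups) > 1 else sub.iloc[0:0]
        for metric in TABLE_ROW_ORDER:
            if len(groups) < 2 or len(a) < 2 or len(b) < 2:
                between.loc[metric, col] = np.nan
            else:
                between.loc[metric, col] = two_sample_t(a[metric], b[metric], variant)

    if bh_correct:
        within = _bh_adjust(within)
        between = _bh_adjust(between)
    return SignificanceTable(within, alpha), SignificanceTable(between, alpha)
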