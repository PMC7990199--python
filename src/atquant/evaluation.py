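"""Method-comparison metrics and report tables.

Dice overlap between AT maps, longitudinal QAT summaries per method and
timepoint, and aggregation of deflation-sensitivity curves.  Tables are plain
pandas DataFrames so any downstream statistics package can consume them.
Sample (n-1) standard deviations are used throughout, matching the usual
"mean (standard deviation)" reporting convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deflation import DeflationCurve
from .volume import BinaryMask


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a.require_same_geometry(b, "masks")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.as_bool() & b.as_bool()))
    return 2.0 * inter / (na + nb)


def longitudinal_table(results: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal QAT summary.

    ``results`` rows need keys ``subject``, ``timepoint``, ``method`` and
    ``qat_percent``.  Returns ``(table, summary)``: the per-measurement table
    augmented with the paired difference to the subject's previous timepoint,
    and the per-(timepoint, method) mean +- sd summary.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(results)
    required = {"subject", "timepoint", "method", "qat_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results missing keys: {sorted(missing)}")
    keys = df[["subject", "timepoint", "method"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, timepoint, method) entry: {dup}")
    df = df.sort_values(["method", "subject", "timepoint"]).reset_index(drop=True)
    df["delta_prev"] = df.groupby(["method", "subject"])["qat_percent"].diff()
    summary = (
        df.groupby(["timepoint", "method"])["qat_percent"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return df, summary


def sensitivity_summary(curves: list[DeflationCurve]) -> pd.DataFrame:
    """Per-beta mean +- sd of the QAT change (QAT(beta) - QAT(1)) per method.

    All curves must share one beta grid.  With a single curve the sd column is
    NaN (flagged, not zero-filled).
    """
    if not curves:
        raise ValueError("no curves to summarize")
    betas = curves[0].betas
    for c in curves[1:]:
        if list(c.betas) != list(betas):
            raise ValueError(f"mismatched beta grids: {c.betas} vs {betas}")
    rows = []
    methods = sorted(curves[0].qat)
    for m in methods:
        deltas = np.array([c.delta_qat[m] for c in curves])  # (n_curves, n_betas)
        for j, beta in enumerate(betas):
            col = deltas[:, j]
            rows.append(
                {
                    "beta": beta,
                    "method": m,
                    "mean_delta_qat": float(col.mean()),
                    "sd_delta_qat": float(np.std(col, ddof=1)) if len(col) > 1 else float("nan"),
                    "n": len(col),
                }
            )
    return pd.DataFrame(rows)
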