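"""Post-surgical welfare analytics from tabular records.

Two record types: a clinical score (sum of eight factors, each rated
0-3, so the total lies in 0-24) and an activity record from
sensor-crossing counts, normalized per animal to the mean activity of
the three days immediately before surgery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_FACTORS = 8
MAX_SUBSCORE = 3

#: the published factor list names seven items for eight factors; the
#: schema therefore treats names as labels only and enforces the count
FACTOR_LABELS = [f"factor_{i + 1}" for i in range(N_FACTORS)]


def total_score(subscores) -> int:
    """Total clinical score: the sum of eight 0-3 subscores (range 0-24)."""
    vals = list(subscores)
    if len(vals) != N_FACTORS:
        raise ValueError(f"expected exactly {N_FACTORS} subscores, got {len(vals)}")
    for v in vals:
        if int(v) != v or not (0 <= int(v) <= MAX_SUBSCORE):
            raise ValueError(f"subscore {v!r} not an integer in 0..{MAX_SUBSCORE}")
    return int(sum(int(v) for v in vals))


def score_table(df: pd.DataFrame, factor_columns=None) -> pd.DataFrame:
    """Add a ``total_score`` column to a per-animal, per-day score table."""
    cols = list(factor_columns) if factor_columns is not None else FACTOR_LABELS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing factor columns: {missing}")
    out = df.copy()
    out["total_score"] = [total_score(row) for row in df[cols].to_numpy()]
    return out


def normalize_activity(
    records: pd.DataFrame,
    surgery_day: int = 0,
    baseline_days: int = 3,
    *,
    subject_col: str = "subject",
    day_col: str = "day",
    crossings_col: str = "crossings",
) -> pd.DataFrame:
    """Normalize sensor-crossing counts to the pre-surgical baseline.

    For each subject, the baseline is the mean crossings over the
    ``baseline_days`` days immediately before ``surgery_day``; every
    day's normalized activity is crossings / baseline.  By construction
    the mean normalized activity over the baseline days is exactly 1.

    Raises if a subject lacks the full pre-surgery window or has a
    non-positive baseline.
    """
    for col in (subject_col, day_col, crossings_col):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    if (records[crossings_col] < 0).any():
        raise ValueError("crossings must be non-negative")
    window = list(range(surgery_day - baseline_days, surgery_day))
    out = []
    for subject, grp in records.groupby(subject_col, sort=False):
        pre = grp[grp[day_col].isin(window)]
        if sorted(pre[day_col]) != window:
            raise ValueError(
                f"subject {subject!r} lacks the {baseline_days} pre-surgery days {window}"
            )
        baseline = float(pre[crossings_col].mean())
        if baseline <= 0:
            raise ValueError(f"subject {subject!r} has zero pre-surgical baseline")
        g = grp.copy()
        g["baseline"] = baseline
        g["normalized_activity"] = g[crossings_col] / baseline
        out.append(g)
    return pd.concat(out, ignore_index=True)


def group_activity_difference(
    normalized: pd.DataFrame,
    group_col: str = "group",
    day_col: str = "day",
    value_col: str = "normalized_activity",
) -> pd.DataFrame:
    """Per-day Welch t-test of normalized activity between two groups."""
    from scipy import stats

    groups = sorted(normalized[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for day, sub in normalized.groupby(day_col):
        a = sub.loc[sub[group_col] == groups[0], value_col].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == groups[1], value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p):
            t, p = 0.0, 1.0
        rows.append({"day": day, "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
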