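"""Relative-net-change (delta) transform and weekly aggregation.

The delta radiomic feature at fraction n is

    DRF_n = (F_1 - F_n) / F_1,   n = 2..N,

i.e. the relative net change from the first fraction; a decrease from
baseline is a *positive* DRF. CA19-9 changes use the identical transform
with the pre-treatment blood sample (fraction 0) as the baseline, so both
biomarker families share one implementation and one sign convention
(positive change = decline = benefit).

Weekly aggregation pools all fraction-level values for all patients within
each treatment week (week = ceil(fraction / 5); a 28-fraction course gives
weeks 1..6 with week 6 covering fractions 26..28 and any sample taken
within two days after the last fraction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import week_of_fraction

__all__ = [
    "relative_net_change",
    "compute_drf",
    "normalize_ca199",
    "aggregate_weekly",
]


def relative_net_change(baseline, value):
    """(baseline - value) / baseline; positive iff the value declined."""
    baseline = np.asarray(baseline, dtype=float)
    return (baseline - np.asarray(value, dtype=float)) / baseline


def _net_change_table(
    df: pd.DataFrame,
    value_col: str,
    baseline_fraction: int,
    group_cols: list[str],
) -> tuple[pd.DataFrame, list[dict]]:
    """Shared delta transform for feature tables and CA19-9 records."""
    skipped: list[dict] = []
    base = df[df["fraction"] == baseline_fraction]
    dup = base.duplicated(group_cols)
    if dup.any():
        raise ValueError(f"duplicate baseline rows for {group_cols}")
    base = base.set_index(group_cols)[value_col]

    out_rows = []
    rest = df[df["fraction"] > baseline_fraction]
    for key, grp in rest.groupby(group_cols, sort=False):
        if len(group_cols) == 1 and isinstance(key, tuple):
            key = key[0]
        if key not in base.index:
            skipped.append({"key": key, "reason": "missing baseline"})
            continue
        b = float(base.loc[key])
        if b == 0:
            skipped.append({"key": key, "reason": "zero baseline"})
            continue
        g = grp.copy()
        g["value"] = (b - g[value_col].to_numpy(dtype=float)) / b
        out_rows.append(g[group_cols + ["fraction", "value"]])
    if out_rows:
        out = pd.concat(out_rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=group_cols + ["fraction", "value"])
    return out, skipped


def compute_drf(
    feature_table: pd.DataFrame, baseline_fraction: int = 1
) -> tuple[pd.DataFrame, list[dict]]:
    """DRF records from a long feature table.

    Parameters
    ----------
    feature_table
        Columns patient_id, fraction, feature, value; fraction 1 rows are
        the baseline.

    Returns the DRF table (patient_id, feature, fraction >= 2, value) and a
    list of skipped (patient, feature) keys with reasons (zero or missing
    baseline). Nothing is imputed.
    """
    df = feature_table.rename(columns={"value": "_raw"})
    out, skipped = _net_change_table(
        df, "_raw", baseline_fraction, ["patient_id", "feature"]
    )
    return out, skipped


def normalize_ca199(
    ca199: pd.DataFrame, baseline_fraction: int = 0
) -> tuple[pd.DataFrame, list[dict]]:
    """Normalized CA19-9 changes relative to the pre-treatment sample.

    Input columns: patient_id, fraction, value. Patients without a
    baseline record are excluded (reported in the skip list); sparse
    schedules are preserved, no interpolation.
    """
    df = ca199.rename(columns={"value": "_raw"})
    out, skipped = _net_change_table(df, "_raw", baseline_fraction, ["patient_id"])
    return out, skipped


def aggregate_weekly(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    value_col: str = "value",
    extra_keys: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pool fraction-level records into (week, group) aggregates.

    Weeks follow ceil(fraction/5). Summary statistics are the pooled n,
    mean, median and quartiles (linear-interpolation convention, matching
    standard boxplots). Groups with no records in a week are emitted with
    n = 0 and NaN statistics.
    """
    df = records.merge(labels[["patient_id", "group"]], on="patient_id", how="left")
    df["week"] = week_of_fraction(df["fraction"])
    keys = ["week", "group", *extra_keys]
    rows = []
    groups = sorted(labels["group"].unique())
    weeks = sorted(df["week"].unique())
    extras = (
        [tuple(x) for x in df[list(extra_keys)].drop_duplicates().to_numpy()]
        if extra_keys
        else [()]
    )
    grouped = {k if isinstance(k, tuple) else (k,): g for k, g in df.groupby(keys)}
    for w in weeks:
        for g in groups:
            for ex in extras:
                sub = grouped.get((w, g, *ex))
                if sub is None or len(sub) == 0:
                    rows.append((w, g, *ex, 0, *([np.nan] * 4)))
                    continue
                v = sub[value_col].to_numpy(dtype=float)
                rows.append(
                    (
                        w, g, *ex, len(v), v.mean(),
                        float(np.quantile(v, 0.5)),
                        float(np.quantile(v, 0.25)),
                        float(np.quantile(v, 0.75)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["week", "group", *extra_keys, "n", "mean", "median", "q1", "q3"]
    )
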