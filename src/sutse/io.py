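"""Reading, writing, and aggregation of monthly count series.

The canonical on-disk format is a tidy CSV with columns ``month`` (ISO
year-month), ``series`` (string label), and ``count`` (positive integer), one
row per (month, series).  Counts must be strictly positive before the natural
log transform; the loader refuses zero or negative counts rather than
silently offsetting them.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .kalman import ObservedSeries

__all__ = [
    "aggregate_incidents",
    "load_monthly_counts",
    "write_monthly_counts",
    "counts_frame_to_observed",
]

logger = logging.getLogger("sutse")


def aggregate_incidents(
    incidents,
    date_column: str,
    category_column: str,
    categories: list[str],
    date_range: tuple[str, str],
) -> pd.DataFrame:
    """Aggregate incident-level records to monthly counts per category.

    Parameters
    ----------
    incidents
        Path to a CSV or a DataFrame with at least the date and category
        columns.  Month boundaries follow the calendar date as written (no
        timezone arithmetic); duplicate records count as separate incidents.
    categories
        Category labels to keep, in output column order.
    date_range
        Inclusive (start, end) bounds; months inside the range with no
        incidents are emitted with count 0.

    Returns
    -------
    Tidy DataFrame with columns month, series, count (every month in range
    present for every category).
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    df = pd.read_csv(incidents) if not isinstance(incidents, pd.DataFrame) else incidents.copy()
    for col in (date_column, category_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    parsed = pd.to_datetime(df[date_column], errors="coerce", format="mixed")
    bad = np.flatnonzero(parsed.isna() & df[date_column].notna())
    if bad.size:
        raise ValueError(f"unparseable dates at row numbers: {bad.tolist()[:20]}")
    present = set(df[category_column].unique())
    unknown = [c for c in categories if c not in present]
    if unknown:
        warnings.warn(f"categories not present in the incident file: {unknown}", stacklevel=2)
    start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    keep = (parsed >= start) & (parsed <= end) & df[category_column].isin(categories)
    sub = pd.DataFrame({"month": parsed[keep].dt.to_period("M"), "series": df.loc[keep, category_column]})
    months = pd.period_range(start.to_period("M"), end.to_period("M"), freq="M")
    tally = sub.groupby(["month", "series"]).size()
    rows = []
    for cat in categories:
        for m in months:
            rows.append({"month": str(m), "series": cat, "count": int(tally.get((m, cat), 0))})
    logger.info("aggregated %d incidents into %d monthly cells", int(keep.sum()), len(rows))
    return pd.DataFrame(rows)


def counts_frame_to_observed(df: pd.DataFrame, allow_missing: bool = False) -> ObservedSeries:
    """Tidy (month, series, count) frame -> ObservedSeries of natural-log counts."""
    required = {"month", "series", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if df.duplicated(["month", "series"]).any():
        raise ValueError("duplicate (month, series) rows")
    series_order = list(pd.unique(df["series"]))
    wide = df.pivot(index="month", columns="series", values="count")[series_order]
    wide.index = pd.PeriodIndex(wide.index.astype(str), freq="M")
    wide = wide.sort_index()
    full = pd.period_range(wide.index[0], wide.index[-1], freq="M")
    if len(full) != len(wide.index) or wide.isna().any().any():
        if not allow_missing:
            missing = [str(m) for m in full if m not in set(wide.index)]
            raise ValueError(
                "missing months in one or more series (pass allow_missing to treat "
                f"gaps as missing data): {missing[:12] or 'ragged series'}"
            )
        wide = wide.reindex(full)
    vals = wide.to_numpy(dtype=float)
    nonpos = np.nan_to_num(vals, nan=1.0) <= 0
    if nonpos.any():
        raise ValueError(
            "counts must be >= 1 before the log transform; found zero or negative "
            "counts. Remove or impute those months explicitly (no silent offset is applied)."
        )
    return ObservedSeries(
        log_counts=np.log(vals),
        months=[str(m) for m in wide.index],
        series_names=[str(s) for s in wide.columns],
    )


def load_monthly_counts(path, allow_missing: bool = False) -> ObservedSeries:
    """Load a monthly-counts CSV and apply the natural log."""
    return counts_frame_to_observed(pd.read_csv(path), allow_missing=allow_missing)


def write_monthly_counts(counts: pd.DataFrame, path) -> None:
    """Write a wide counts table (PeriodIndex x series) as the tidy CSV schema."""
    rows = [
        {"month": str(m), "series": str(s), "count": int(v)}
        for s in counts.columns
        for m, v in counts[s].items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
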