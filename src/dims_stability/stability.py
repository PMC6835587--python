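"""Fold-change stability classification against the analysis-variability band.

For every metabolite and storage condition the fold change (FC) is the
condition intensity divided by the reference intensity, computed per pool.
Across pools the mean FC and its 95% confidence interval are formed
(t-based by default; a min-max range method is available).  A metabolite is
called ``increased`` when the CI's lower limit lies strictly above the band
1 + MAV, ``decreased`` when the upper limit lies strictly below 1 - MAV,
otherwise ``unaffected``; with fewer than two usable pools the call is
``undefined`` and the metabolite is excluded from the affected counts.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedMatrix
from .library import MetaboliteLibrary
from .synthetic import REFERENCE_SERIES, StudyDesign

log = logging.getLogger(__name__)

CALLS = ("increased", "decreased", "unaffected", "undefined")


def fold_change(sample_intensity: float, reference_intensity: float) -> float:
    """FC = sample / reference; NaN (undefined) when the reference is not positive."""
    if not np.isfinite(reference_intensity) or reference_intensity <= 0:
        log.warning("fold change undefined: non-positive reference intensity")
        return float("nan")
    return float(sample_intensity) / float(reference_intensity)


def fc_confidence_interval(
    fcs: Sequence[float],
    level: float = 0.95,
    method: str = "t",
) -> tuple[float, float, float]:
    """(center, low, high) across pools.

    ``t``: center = mean, half-width = t_{(1+level)/2, n-1} * sd / sqrt(n).
    ``minmax``: center = mean, interval = observed range.
    """
    x = np.asarray([f for f in fcs if np.isfinite(f)], dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval needs at least two fold changes")
    center = float(x.mean())
    if method == "t":
        half = float(
            stats.t.ppf(0.5 + level / 2.0, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
        )
        return center, center - half, center + half
    if method == "minmax":
        return center, float(x.min()), float(x.max())
    raise ValueError(f"unknown CI method {method!r}")


def classify(ci_low: float, ci_high: float, mav: float) -> str:
    """Three-way call with strict comparisons against the band 1 +/- MAV."""
    if mav < 0:
        raise ValueError("mav must be non-negative")
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        return "undefined"
    if ci_low > 1.0 + mav:
        return "increased"
    if ci_high < 1.0 - mav:
        return "decreased"
    return "unaffected"


def compute_stability(
    annotated: AnnotatedMatrix,
    design: StudyDesign,
    mav_by_series: Mapping[str, float],
    ci_method: str = "t",
    include_silc: bool = False,
    library: MetaboliteLibrary | None = None,
) -> pd.DataFrame:
    """StabilityRecords for every metabolite x condition in the design.

    One row per (metabolite, series, level) with per-pool fold changes, the
    CI, the series band and the call.  Pools whose reference intensity is
    non-positive are dropped per metabolite (logged tally); records with
    fewer than two surviving pools are ``undefined``.  sILC entries are
    excluded unless ``include_silc``.
    """
    meta = annotated.sample_meta
    values = annotated.values
    mets = list(values.index)
    if not include_silc and library is not None:
        silc = set(library.silc_names)
        mets = [m for m in mets if m not in silc]

    pools = sorted(meta["pool"].unique())
    ref_cols = {
        p: meta[(meta["pool"] == p) & (meta["series"] == REFERENCE_SERIES)].index
        for p in pools
    }
    ref = np.column_stack(
        [
            values[ref_cols[p][0]].to_numpy()
            if len(ref_cols[p])
            else np.full(len(values), np.nan)
            for p in pools
        ]
    )
    ref = pd.DataFrame(ref, index=values.index, columns=pools).loc[mets]
    n_dropped_pools = int(((ref <= 0) | ~np.isfinite(ref)).to_numpy().sum())
    if n_dropped_pools:
        log.info(
            "dropping %d metabolite x pool fold changes (non-positive reference)",
            n_dropped_pools,
        )

    rows = []
    base = meta.reset_index()
    conditions = (
        base[base["series"] != REFERENCE_SERIES][["series", "level"]]
        .drop_duplicates()
        .sort_values(["series", "level"])
    )
    for series, level in conditions.itertuples(index=False):
        mav = float(mav_by_series[series])
        cols = {}
        for p in pools:
            sel = base[
                (base["pool"] == p) & (base["series"] == series) & (base["level"] == level)
            ]
            cols[p] = sel["sample_id"].iloc[0] if len(sel) else None
        fc = np.full((len(mets), len(pools)), np.nan)
        for j, p in enumerate(pools):
            if cols[p] is None:
                continue
            num = values.loc[mets, cols[p]].to_numpy(float)
            den = ref[p].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = num / den
            f[~np.isfinite(den) | (den <= 0)] = np.nan
            fc[:, j] = f
        n_ok = np.isfinite(fc).sum(axis=1)
        mean = np.nanmean(np.where(np.isfinite(fc), fc, np.nan), axis=1)
        sd = _nanstd1(fc)
        if ci_method == "t":
            with np.errstate(invalid="ignore"):
                half = stats.t.ppf(0.975, np.maximum(n_ok - 1, 1)) * sd / np.sqrt(n_ok)
            low, high = mean - half, mean + half
        elif ci_method == "minmax":
            low, high = np.nanmin(fc, axis=1), np.nanmax(fc, axis=1)
        else:
            raise ValueError(f"unknown CI method {ci_method!r}")
        calls = np.where(
            n_ok < 2,
            "undefined",
            np.where(
                low > 1.0 + mav,
                "increased",
                np.where(high < 1.0 - mav, "decreased", "unaffected"),
            ),
        )
        frame = pd.DataFrame(
            {
                "metabolite": mets,
                "series": series,
                "level": level,
                "n_pools": n_ok,
                "center": mean,
                "ci_low": low,
                "ci_high": high,
                "band_low": 1.0 - mav,
                "band_high": 1.0 + mav,
                "call": calls,
            }
        )
        for j, p in enumerate(pools):
            frame[f"fc_pool{p}"] = fc[:, j]
        rows.append(frame)
    records = pd.concat(rows, ignore_index=True)
    n_undef = int((records["call"] == "undefined").sum())
    if n_undef:
        log.info("%d records undefined (fewer than two usable pools)", n_undef)
    return records


def _nanstd1(fc: np.ndarray) -> np.ndarray:
    """Row-wise sample std over finite entries; NaN where fewer than 2."""
    out = np.full(fc.shape[0], np.nan)
    n = np.isfinite(fc).sum(axis=1)
    ok = n >= 2
    if ok.any():
        with np.errstate(invalid="ignore"):
            masked = np.where(np.isfinite(fc), fc, np.nan)
            out[ok] = np.array(
                [np.nanstd(row, ddof=1) for row in masked[ok]]
            )
    return out


def extreme_records(records: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Restrict records to the most extreme level of each series."""
    keep = []
    for series in records["series"].unique():
        extreme = design.extreme_level(series)
        keep.append(records[(records["series"] == series) & (records["level"] == extreme)])
    return pd.concat(keep, ignore_index=True) if keep else records.iloc[0:0]


def count_affected(records: pd.DataFrame, panel: set[str] | None = None) -> pd.DataFrame:
    """Tally calls per series: n_decreased, n_increased, n_total_affected.

    ``panel`` restricts the tally to a metabolite subset (e.g. the
    neurometabolic panel); ``undefined`` records never count as affected.
    """
    sub = records if panel is None else records[records["metabolite"].isin(panel)]
    out = {}
    for series in sorted(sub["series"].unique()):
        grp = sub[sub["series"] == series]
        n_dec = int((grp["call"] == "decreased").sum())
        n_inc = int((grp["call"] == "increased").sum())
        out[series] = {
            "n_decreased": n_dec,
            "n_increased": n_inc,
            "n_total_affected": n_dec + n_inc,
            "n_undefined": int((grp["call"] == "undefined").sum()),
            "n_records": len(grp),
        }
    if not out:
        return pd.DataFrame(
            columns=[
                "n_decreased", "n_increased", "n_total_affected",
                "n_undefined", "n_records",
            ]
        )
    return pd.DataFrame.from_dict(out, orient="index")


def stability_plot_table(
    records: pd.DataFrame,
    design: StudyDesign,
    library: MetaboliteLibrary,
    series: str,
) -> pd.DataFrame:
    """Per-metabolite table for the extreme condition of one series, shaped
    for a fold-change plot: center, CI limits, band and group label."""
    extreme = design.extreme_level(series)
    sub = records[(records["series"] == series) & (records["level"] == extreme)].copy()
    groups = library.entries.set_index("name")["group"]
    sub["group"] = sub["metabolite"].map(groups).fillna("")
    cols = [
        "metabolite", "group", "center", "ci_low", "ci_high",
        "band_low", "band_high", "call",
    ]
    return sub[cols].reset_index(drop=True)


def plot_stability(plot_table: pd.DataFrame, ax=None, title: str = ""):
    """Fold-change plot: per metabolite the mean FC (dot) and 95% CI
    (vertical line), with dashed lines at the analysis-variability band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(plot_table) * 0.12), 4))
    x = np.arange(len(plot_table))
    ax.vlines(x, plot_table["ci_low"], plot_table["ci_high"], color="tab:blue", lw=1)
    ax.plot(x, plot_table["center"], "o", color="tab:red", ms=3)
    if len(plot_table):
        ax.axhline(1.0, color="black", lw=1)
        ax.axhline(float(plot_table["band_low"].iloc[0]), ls="--", color="grey", lw=1)
        ax.axhline(float(plot_table["band_high"].iloc[0]), ls="--", color="grey", lw=1)
    ax.set_xlabel("metabolite index")
    ax.set_ylabel("fold change vs reference")
    if title:
        ax.set_title(title)
    return ax
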