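"""Technical (analysis) variability from stable-isotope-labelled compounds.

Spiked sILCs see every storage condition at a fixed true concentration, so
their spread across the run measures analysis variability alone.  Two
summaries are computed per sILC:

* the coefficient of variation (CV), sample standard deviation divided by
  the mean, over all included samples in the run; and
* the median absolute variation (MAV) for the most extreme condition of each
  storage series: per pool the fold change of the extreme condition against
  the reference, minus 1, in absolute value, then the median across pools.

The median MAV across sILCs per series defines the analysis-variability
fold-change band 1 +/- MAV used by the stability classifier.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedMatrix
from .library import MetaboliteLibrary
from .synthetic import REFERENCE_SERIES, StudyDesign

log = logging.getLogger(__name__)


def coefficient_of_variation(intensities: Sequence[float]) -> float:
    """Sample CV: standard deviation (n-1 denominator) over mean."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    if np.all(x == 0):
        raise ValueError("CV undefined for all-zero intensities")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean intensity")
    return float(x.std(ddof=1) / mean)


def median_absolute_variation(
    extreme_intensity_per_pool: Sequence[float],
    reference_intensity_per_pool: Sequence[float],
) -> float:
    """Median over pools of |extreme/reference - 1|.

    Pools with a non-positive or missing reference are excluded with a
    warning; if no pool survives the result is NaN (flagged undefined).
    """
    ext = np.asarray(extreme_intensity_per_pool, dtype=float)
    ref = np.asarray(reference_intensity_per_pool, dtype=float)
    if ext.shape != ref.shape:
        raise ValueError("extreme and reference vectors must be pool-paired")
    ok = np.isfinite(ref) & (ref > 0) & np.isfinite(ext)
    if (~ok).any():
        log.warning(
            "median_absolute_variation: excluding %d pool(s) with unusable reference",
            int((~ok).sum()),
        )
    if not ok.any():
        log.warning("median_absolute_variation undefined: no usable pools")
        return float("nan")
    return float(np.median(np.abs(ext[ok] / ref[ok] - 1.0)))


def qc_summary(
    per_silc_values: Sequence[float],
    probs: Sequence[float] = (0.05, 0.5, 0.95),
    method: str = "linear",
) -> pd.Series:
    """Quantile summary rows (default 5th percentile, median, 95th).

    The quantile ``method`` is any numpy interpolation rule; the median is
    method-independent for odd-length input.
    """
    x = np.asarray(per_silc_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value list")
    probs = list(probs)
    if any(not (0.0 < p < 1.0) for p in probs):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    q = np.quantile(x, probs, method=method)
    return pd.Series(q, index=[f"p{int(round(p * 100)):02d}" for p in probs])


def silc_qc_table(
    annotated: AnnotatedMatrix,
    design: StudyDesign,
    library: MetaboliteLibrary,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Per-sILC CV and per-series extreme-condition MAV, plus summary rows.

    Output rows are the sILCs in library order followed by ``p05``,
    ``median`` and ``p95`` summary rows; columns are ``cv`` and ``mav_<series>``
    for every condition series in the design.
    """
    silc = library.silc_names
    if not silc:
        raise ValueError("library contains no sILC entries")
    meta = annotated.sample_meta
    series_list = design.condition_series()

    records = {}
    for name in silc:
        row = {"cv": coefficient_of_variation(annotated.values.loc[name])}
        for series in series_list:
            row[f"mav_{series}"] = _extreme_mav(annotated, meta, name, series, design)
        records[name] = row
    table = pd.DataFrame.from_dict(records, orient="index")

    summary = {}
    for stat, p in (("p05", 0.05), ("median", 0.5), ("p95", 0.95)):
        summary[stat] = {
            col: float(qc_summary(table[col].dropna(), [p], quantile_method).iloc[0])
            for col in table.columns
        }
    return pd.concat([table, pd.DataFrame.from_dict(summary, orient="index")])


def _extreme_mav(
    annotated: AnnotatedMatrix,
    meta: pd.DataFrame,
    metabolite: str,
    series: str,
    design: StudyDesign,
) -> float:
    extreme = design.extreme_level(series)
    ext, ref = [], []
    for pool in sorted(meta["pool"].unique()):
        sel_ext = meta[(meta["pool"] == pool) & (meta["series"] == series) & (meta["level"] == extreme)]
        sel_ref = meta[(meta["pool"] == pool) & (meta["series"] == REFERENCE_SERIES)]
        if sel_ext.empty or sel_ref.empty:
            continue  # e.g. the extreme sample of this pool was excluded
        ext.append(float(annotated.values.loc[metabolite, sel_ext.index[0]]))
        ref.append(float(annotated.values.loc[metabolite, sel_ref.index[0]]))
    if not ext:
        return float("nan")
    return median_absolute_variation(ext, ref)


def variability_bands(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Analysis-variability bands per series from the qc table's median row.

    Returns a DataFrame indexed by series with columns ``mav, band_low,
    band_high`` where band = 1 -/+ MAV, so band_low + band_high == 2.
    """
    med = qc_table.loc["median"]
    out = {}
    for col in qc_table.columns:
        if not col.startswith("mav_"):
            continue
        mav = float(med[col])
        out[col[len("mav_"):]] = {
            "mav": mav,
            "band_low": 1.0 - mav,
            "band_high": 1.0 + mav,
        }
    return pd.DataFrame.from_dict(out, orient="index")
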