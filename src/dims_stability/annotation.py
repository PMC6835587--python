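"""Peak annotation: ppm matching to a mass library and adduct summation.

A measured peak at m/z ``x`` matches a metabolite-adduct channel with
theoretical m/z ``t`` iff ``|x - t| / t * 1e6 <= tol_ppm`` (inclusive,
default 2 ppm).  A peak may match several metabolites (isomers, mass
collisions); all matches are retained.  Per metabolite and sample the
intensities of the five adduct channels are added into one summed intensity,
and technical replicates are then aggregated (mean by default) to a single
value per design sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .adducts import DEFAULT_ADDUCTS, SCAN_WINDOW, AdductRule, compute_adduct_mz
from .library import MetaboliteLibrary
from .synthetic import StudyDesign

log = logging.getLogger(__name__)

__all__ = [
    "AdductRule",
    "compute_adduct_mz",
    "match_peaks",
    "summed_intensities",
    "AnnotatedMatrix",
]


def _channel_table(
    library: MetaboliteLibrary,
    adducts: tuple[AdductRule, ...],
    window: tuple[float, float],
) -> pd.DataFrame:
    """All in-window (metabolite, adduct) theoretical m/z channels."""
    mets = library.entries
    rows = []
    for adduct in adducts:
        theo = mets["monoisotopic_mass"].to_numpy(float) + adduct.mass_shift
        keep = (theo >= window[0]) & (theo <= window[1])
        rows.append(
            pd.DataFrame(
                {
                    "metabolite": mets["name"].to_numpy()[keep],
                    "adduct": adduct.label,
                    "theoretical_mz": theo[keep],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["metabolite", "adduct", "theoretical_mz"]
    )
    return out.sort_values("theoretical_mz", kind="mergesort").reset_index(drop=True)


def match_peaks(
    peaks: pd.DataFrame,
    library: MetaboliteLibrary,
    tol_ppm: float = 2.0,
    *,
    adducts: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    scan_window: tuple[float, float] = SCAN_WINDOW,
) -> pd.DataFrame:
    """Match measured peaks to library adduct channels within ``tol_ppm``.

    ``peaks`` needs columns ``sample_id, replicate, mz, intensity``.  Peaks
    outside the scan window are dropped (count logged).  Returns the match
    set as a long DataFrame with one row per (peak, channel) pair, carrying
    the peak columns plus ``metabolite, adduct, theoretical_mz, ppm_error``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    required = {"sample_id", "replicate", "mz", "intensity"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["intensity"] < 0).any():
        raise ValueError("negative intensities in peak table")

    lo, hi = scan_window
    in_win = (peaks["mz"] >= lo) & (peaks["mz"] <= hi)
    n_dropped = int((~in_win).sum())
    if n_dropped:
        log.info("dropped %d peaks outside scan window [%g, %g]", n_dropped, lo, hi)
    peaks = peaks[in_win].reset_index(drop=True)

    channels = _channel_table(library, adducts, scan_window)
    if peaks.empty or channels.empty:
        return pd.DataFrame(
            columns=list(peaks.columns)
            + ["metabolite", "adduct", "theoretical_mz", "ppm_error"]
        )

    theo = channels["theoretical_mz"].to_numpy()
    mz = peaks["mz"].to_numpy()
    eps = tol_ppm * 1e-6
    # |x - t| <= t*eps  <=>  t in [x/(1+eps), x/(1-eps)]
    i0 = np.searchsorted(theo, mz / (1.0 + eps), side="left")
    i1 = np.searchsorted(theo, mz / (1.0 - eps), side="right")
    counts = i1 - i0
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(
            columns=list(peaks.columns)
            + ["metabolite", "adduct", "theoretical_mz", "ppm_error"]
        )
    peak_idx = np.repeat(np.arange(len(mz)), counts)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    chan_idx = np.repeat(i0, counts) + (np.arange(total) - starts)

    out = peaks.iloc[peak_idx].reset_index(drop=True)
    out["metabolite"] = channels["metabolite"].to_numpy()[chan_idx]
    out["adduct"] = channels["adduct"].to_numpy()[chan_idx]
    out["theoretical_mz"] = theo[chan_idx]
    out["ppm_error"] = (out["mz"] - out["theoretical_mz"]) / out["theoretical_mz"] * 1e6
    # inclusive boundary, re-checked exactly (searchsorted bounds can admit
    # float round-off at the window edge)
    out = out[out["ppm_error"].abs() <= tol_ppm].reset_index(drop=True)
    log.info("matched %d of %d peaks to %d channels", len(out), len(mz), len(channels))
    return out


@dataclass
class AnnotatedMatrix:
    """Summed intensity per metabolite annotation x design sample.

    ``values``: metabolites x samples, replicate-aggregated summed adduct
    intensities (0 where nothing was detected).  ``detected`` flags cells with
    at least one contributing peak.  ``replicate_values`` keeps the
    per-replicate sums; ``matches`` is the per-peak provenance;
    ``sample_meta`` maps sample_id -> (pool, series, level).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    replicate_values: pd.DataFrame
    matches: pd.DataFrame
    sample_meta: pd.DataFrame

    def panel_subset(self, library: MetaboliteLibrary) -> "AnnotatedMatrix":
        keep = [m for m in self.values.index if m in set(library.panel_names)]
        return AnnotatedMatrix(
            self.values.loc[keep],
            self.detected.loc[keep],
            self.replicate_values[self.replicate_values["metabolite"].isin(keep)],
            self.matches[self.matches["metabolite"].isin(keep)]
            if len(self.matches)
            else self.matches,
            self.sample_meta,
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, float_format="%.10g")

    def provenance_json(self, path: str | Path) -> None:
        cols = ["metabolite", "sample_id", "replicate", "adduct", "mz", "intensity"]
        recs = self.matches[cols].to_dict(orient="records") if len(self.matches) else []
        with open(path, "w") as fh:
            json.dump(recs, fh, indent=None, sort_keys=True, default=float)


def summed_intensities(
    matches: pd.DataFrame,
    library: MetaboliteLibrary,
    design: StudyDesign,
    replicate_agg: str = "mean",
) -> AnnotatedMatrix:
    """Sum matched peak intensities over adduct channels and aggregate
    technical replicates to one value per design sample.

    Missing channels contribute 0; multiple peaks matching one channel in one
    replicate are summed.  Replicates absent from the match set contribute a
    sum of 0 (a replicate with nothing detected is a measured zero, not a
    missing measurement).  Excluded design samples are skipped entirely.
    """
    if replicate_agg not in ("mean", "median"):
        raise ValueError("replicate_agg must be 'mean' or 'median'")
    included = design.included()
    sample_ids = included["sample_id"].drop_duplicates().tolist()
    if len(matches):
        unknown = set(matches["sample_id"]) - set(design.samples["sample_id"])
        if unknown:
            raise KeyError(f"matches reference unknown samples: {sorted(unknown)}")

    mets = library.names
    meas = included[["sample_id", "replicate"]].drop_duplicates()
    grid = pd.MultiIndex.from_frame(
        pd.merge(meas, pd.DataFrame({"metabolite": mets}), how="cross")[
            ["metabolite", "sample_id", "replicate"]
        ]
    )
    if len(matches):
        usable = matches[matches["sample_id"].isin(sample_ids)]
        sums = usable.groupby(["metabolite", "sample_id", "replicate"])[
            "intensity"
        ].sum()
    else:
        usable = matches
        sums = pd.Series(dtype=float)
    rep = sums.reindex(grid, fill_value=0.0).rename("intensity").reset_index()

    agg = getattr(rep.groupby(["metabolite", "sample_id"])["intensity"], replicate_agg)()
    values = (
        agg.unstack("sample_id")
        .reindex(index=mets, columns=sample_ids)
        .fillna(0.0)
    )
    if len(usable):
        det = (
            usable.groupby(["metabolite", "sample_id"])
            .size()
            .unstack("sample_id")
            .reindex(index=mets, columns=sample_ids)
            .notna()
        )
    else:
        det = pd.DataFrame(False, index=mets, columns=sample_ids)
    n_missing = int((~det).to_numpy().sum())
    if n_missing:
        log.info("%d metabolite x sample cells not detected (set to 0)", n_missing)

    meta = (
        design.base_samples()
        .set_index("sample_id")
        .loc[sample_ids, ["pool", "series", "level"]]
    )
    return AnnotatedMatrix(values, det, rep, usable.reset_index(drop=True), meta)
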