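"""Synthetic study generator for a CSF storage-stability experiment.

Emulates the design of a pre-analytical stability study: P CSF pools, each
split into one reference aliquot (immediately frozen at -80 degC) and a grid
of storage conditions over four series — repeated freeze/thaw cycles and
storage at -20 degC, 5-8 degC ("fridge") or 18-22 degC ("room") for
increasing durations — measured in technical triplicate by direct infusion.

Peak tables contain, per metabolite, peaks at the five adduct m/z channels.
Intensity for metabolite m in pool p, condition (s, l), replicate r is

    baseline_m * frac_a * pool_factor_p * drift_m(s, l) * exp(eps)

with eps ~ Normal(0, noise_sigma^2) drawn once per metabolite x infusion
replicate and shared across the five adduct peaks, so the summed intensity
of a metabolite is exactly lognormal with CV sqrt(exp(sigma^2) - 1).
Technical replicates share the sample-level drift and differ only by this
replicate noise; spike-in sILC channels have drift identically 1 and, being
added at fixed concentration during sample preparation, ignore the per-pool
biological scale factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adducts import DEFAULT_ADDUCTS, SCAN_WINDOW
from .library import MetaboliteLibrary

log = logging.getLogger(__name__)

REFERENCE_SERIES = "reference"

#: Default 22-condition grid: 7 freeze/thaw cycles, -20 degC for 1-4 months,
#: 5-8 degC for 8 h to 1 week, 18-22 degC for 2 h to 1 week.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "freeze_thaw": (1, 2, 3, 4, 5, 6, 7),
    "minus20": (1, 2, 3, 4),
    "fridge": (8, 24, 48, 72, 168),
    "room": (2, 8, 24, 48, 72, 168),
}

#: Fixed split of a metabolite's total intensity over the five adduct channels.
DEFAULT_ADDUCT_FRACTIONS: dict[str, float] = {
    "[M+H]+": 0.35,
    "[M-H]-": 0.30,
    "[M+Na]+": 0.15,
    "[M+K]+": 0.10,
    "[M+Cl]-": 0.10,
}

DESIGN_COLUMNS = ("sample_id", "pool", "series", "level", "replicate", "excluded")


@dataclass
class StudyDesign:
    """Long table of measurements: one row per design sample x replicate."""

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        base = df.drop_duplicates("sample_id")
        refs = base[base["series"] == REFERENCE_SERIES].groupby("pool").size()
        for pool in base["pool"].unique():
            if refs.get(pool, 0) != 1:
                raise ValueError(
                    f"pool {pool} must have exactly one reference sample, "
                    f"found {refs.get(pool, 0)}"
                )
        for (pool, series), grp in base[base["series"] != REFERENCE_SERIES].groupby(
            ["pool", "series"]
        ):
            levels = grp["level"].to_numpy()
            if len(np.unique(levels)) != len(levels) or not np.all(np.diff(levels) > 0):
                raise ValueError(
                    f"levels within series {series!r} (pool {pool}) must be "
                    "strictly increasing and unique"
                )
        self.samples = df.reset_index(drop=True)

    @property
    def n_pools(self) -> int:
        return self.samples["pool"].nunique()

    @property
    def replicates(self) -> int:
        return int(self.samples["replicate"].max())

    def base_samples(self) -> pd.DataFrame:
        """One row per design sample (before replicate expansion)."""
        return self.samples.drop_duplicates("sample_id").drop(columns=["replicate"])

    def included(self) -> pd.DataFrame:
        return self.samples[~self.samples["excluded"]]

    def series_levels(self, series: str) -> list[float]:
        sub = self.base_samples()
        return sorted(sub.loc[sub["series"] == series, "level"].unique())

    def extreme_level(self, series: str) -> float:
        levels = self.series_levels(series)
        if not levels:
            raise KeyError(f"series {series!r} not present in design")
        return levels[-1]

    def condition_series(self) -> list[str]:
        out = [s for s in self.base_samples()["series"].unique() if s != REFERENCE_SERIES]
        return list(out)

    def exclude(self, sample_ids: Sequence[str]) -> "StudyDesign":
        """Return a copy with the given design samples flagged excluded."""
        df = self.samples.copy()
        unknown = set(sample_ids) - set(df["sample_id"])
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        df.loc[df["sample_id"].isin(sample_ids), "excluded"] = True
        return StudyDesign(df)

    def to_tsv(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t")
        df["excluded"] = df["excluded"].astype(bool)
        return cls(df)


def sample_id(pool: int, series: str, level: float) -> str:
    if series == REFERENCE_SERIES:
        return f"P{pool}_reference"
    lvl = f"{level:g}"
    return f"P{pool}_{series}_{lvl}"


def generate_design(
    pools: int,
    grid: Mapping[str, Sequence[float]] | None = None,
    replicates: int = 1,
) -> StudyDesign:
    """Build the study design: per pool one reference plus one sample per
    grid condition, expanded to ``replicates`` technical replicates.

    With the default grid (22 conditions) and 3 pools this yields 69 design
    samples, matching a reference-plus-22-condition layout per pool.
    """
    if pools < 1:
        raise ValueError("need at least one pool")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if grid is None:
        grid = DEFAULT_GRID
    rows = []
    for pool in range(1, pools + 1):
        rows.append((sample_id(pool, REFERENCE_SERIES, 0), pool, REFERENCE_SERIES, 0.0))
        for series, levels in grid.items():
            lv = [float(x) for x in levels]
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate levels in series {series!r}")
            for level in sorted(lv):
                rows.append((sample_id(pool, series, level), pool, series, level))
    base = pd.DataFrame(rows, columns=["sample_id", "pool", "series", "level"])
    expanded = base.loc[base.index.repeat(replicates)].reset_index(drop=True)
    expanded["replicate"] = np.tile(np.arange(1, replicates + 1), len(base))
    expanded["excluded"] = False
    return StudyDesign(expanded)


DriftSpec = Callable[[float], float] | Mapping[float, float] | float


@dataclass
class EffectSpec:
    """Ground truth for the generator.

    ``drifts`` maps metabolite name -> series -> drift, where drift is a
    constant fold change applied at every level of the series, a
    ``{level: fold_change}`` mapping (levels absent from the mapping get 1),
    or a callable of the level.  Reference samples always have drift 1, as do
    sILC entries (enforced).  ``pool_factors`` are global per-pool intensity
    scales; ``noise_sigma`` is the standard deviation of the per-replicate
    log-intensity technical noise.
    """

    drifts: Mapping[str, Mapping[str, DriftSpec]] = field(default_factory=dict)
    pool_factors: Sequence[float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    dropout_rate: float = 0.0
    mz_jitter_ppm: float = 0.0
    baseline_log10_range: tuple[float, float] = (5.0, 7.0)
    adduct_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_FRACTIONS)
    )

    def drift(self, metabolite: str, series: str, level: float) -> float:
        spec = self.drifts.get(metabolite, {}).get(series)
        if spec is None or series == REFERENCE_SERIES:
            return 1.0
        if callable(spec):
            value = float(spec(level))
        elif isinstance(spec, Mapping):
            # level keys may arrive as int or str from YAML/JSON configs
            by_level = {float(k): v for k, v in spec.items()}
            value = float(by_level.get(float(level), 1.0))
        else:
            value = float(spec)
        if value <= 0:
            raise ValueError(
                f"drift for {metabolite!r} in series {series!r} must be positive"
            )
        return value

    def validate_against(self, library: MetaboliteLibrary) -> None:
        known = set(library.names)
        silc = set(library.silc_names)
        for met in self.drifts:
            if met not in known:
                raise KeyError(f"effect spec references unknown metabolite {met!r}")
            if met in silc:
                raise ValueError(
                    f"sILC entry {met!r} cannot carry a storage drift (must stay 1)"
                )


def simulate_peak_tables(
    library: MetaboliteLibrary,
    design: StudyDesign,
    effects: EffectSpec,
) -> pd.DataFrame:
    """Generate the long peak table for every design row and replicate.

    Returns a DataFrame with columns ``sample_id, replicate, polarity, mz,
    intensity``; peaks whose adduct m/z falls outside the scan window are not
    emitted.  Excluded design rows are still generated (exclusion is a
    downstream decision).  Deterministic for a fixed ``effects.seed``.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    effects.validate_against(library)

    rng = np.random.default_rng(effects.seed)
    mets = library.entries
    n_met = len(mets)
    masses = mets["monoisotopic_mass"].to_numpy(float)
    names = mets["name"].to_numpy()

    lo10, hi10 = effects.baseline_log10_range
    baselines = 10.0 ** rng.uniform(lo10, hi10, size=n_met)

    rows = design.samples
    n_rows = len(rows)
    pools = rows["pool"].to_numpy()
    pool_ids = sorted(rows["pool"].unique())
    if effects.pool_factors is None:
        pf = {p: 1.0 for p in pool_ids}
    else:
        if len(effects.pool_factors) != len(pool_ids):
            raise ValueError("pool_factors length must equal number of pools")
        pf = {p: float(f) for p, f in zip(pool_ids, effects.pool_factors)}
        if any(v <= 0 for v in pf.values()):
            raise ValueError("pool factors must be positive")
    pool_scale = np.array([pf[p] for p in pools])
    # sILCs are spiked at a fixed concentration during preparation: their
    # abundance does not follow the pool's biological scale
    is_silc = mets["is_silc"].to_numpy(bool)

    # drift per design sample x metabolite (replicates share the drift)
    base = rows[["sample_id", "series", "level"]].drop_duplicates("sample_id")
    drift_by_sample = {}
    for sid, series, level in base.itertuples(index=False):
        drift_by_sample[sid] = np.array(
            [effects.drift(m, series, level) for m in names]
        )
    drift = np.vstack([drift_by_sample[s] for s in rows["sample_id"]])

    eps = rng.normal(0.0, effects.noise_sigma, size=(n_rows, n_met)) \
        if effects.noise_sigma > 0 else np.zeros((n_rows, n_met))

    # metabolite x row summed intensity, split over adduct channels
    scale = np.where(is_silc[None, :], 1.0, pool_scale[:, None])
    summed = baselines[None, :] * scale * drift * np.exp(eps)

    adducts = [a for a in DEFAULT_ADDUCTS]
    fractions = np.array([effects.adduct_fractions[a.label] for a in adducts])
    theo = masses[:, None] + np.array([a.mass_shift for a in adducts])[None, :]
    lo, hi = SCAN_WINDOW
    in_window = (theo >= lo) & (theo <= hi)

    frames = []
    met_idx = np.arange(n_met)
    for k, adduct in enumerate(adducts):
        keep = in_window[:, k]
        if not keep.any():
            continue
        mz_k = theo[keep, k]
        inten = summed[:, keep] * fractions[k]  # rows x kept mets
        n_keep = keep.sum()
        frame = pd.DataFrame(
            {
                "sample_id": np.repeat(rows["sample_id"].to_numpy(), n_keep),
                "replicate": np.repeat(rows["replicate"].to_numpy(), n_keep),
                "polarity": adduct.polarity,
                "mz": np.tile(mz_k, n_rows),
                "intensity": inten.ravel(),
                "_met": np.tile(met_idx[keep], n_rows),
                "_adduct_order": k,
            }
        )
        frames.append(frame)
    peaks = pd.concat(frames, ignore_index=True)

    if effects.mz_jitter_ppm > 0:
        jitter = rng.normal(0.0, effects.mz_jitter_ppm * 1e-6, size=len(peaks))
        peaks["mz"] = peaks["mz"] * (1.0 + jitter)
    if effects.dropout_rate > 0:
        keep_mask = rng.random(len(peaks)) >= effects.dropout_rate
        peaks = peaks[keep_mask]

    peaks = (
        peaks.sort_values(["sample_id", "replicate", "_adduct_order", "_met"])
        .drop(columns=["_met", "_adduct_order"])
        .reset_index(drop=True)
    )
    log.info(
        "simulated %d peaks for %d measurements x %d metabolites",
        len(peaks), n_rows, n_met,
    )
    return peaks


def write_peak_tables(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, index=False, float_format="%.10g")


def read_peak_tables(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
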