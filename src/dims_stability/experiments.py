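"""Canned synthetic experiments: classifier recovery and global-null runs.

These compose the generator, annotation, QC and stability/statistics stages
into the study-level checks used throughout the project: how reliably the
fold-change classifier recovers injected storage drifts of known size, and
how the battery behaves when no drift exists at all.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import match_peaks, summed_intensities
from .library import generate_library
from .qc import silc_qc_table, variability_bands
from .stability import compute_stability, count_affected, extreme_records
from .stats import feature_tests
from .synthetic import EffectSpec, generate_design, simulate_peak_tables


def drifter_recovery_experiment(
    seed: int,
    n_metabolites: int = 500,
    n_silc: int = 17,
    frac_drifters: float = 0.10,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    noise_sigma: float = 0.07,
    pools: int = 3,
    replicates: int = 3,
    series: str = "freeze_thaw",
    level: float = 7.0,
) -> dict[str, float]:
    """Inject known drifts at one extreme condition and score the classifier.

    A fraction of metabolites receives a true fold change of ``fc_up`` (half)
    or ``fc_down`` (half) at the condition; the rest are null.  Returns the
    sensitivity (drifters flagged in the correct direction), the false-flag
    rate among null metabolites, and the band half-width used.
    """
    lib = generate_library(n_metabolites + n_silc, (70, 600), n_silc, seed=seed)
    design = generate_design(pools, {series: [level]}, replicates)
    mets = [n for n in lib.names if not n.startswith("silc")]
    rng = np.random.default_rng(seed + 1)
    n_drift = int(round(frac_drifters * len(mets)))
    drifters = list(rng.choice(mets, size=n_drift, replace=False))
    up = set(drifters[: n_drift // 2])
    down = set(drifters[n_drift // 2:])
    drifts = {m: {series: {level: fc_up if m in up else fc_down}} for m in drifters}

    eff = EffectSpec(drifts=drifts, noise_sigma=noise_sigma, seed=seed + 2)
    peaks = simulate_peak_tables(lib, design, eff)
    ann = summed_intensities(match_peaks(peaks, lib), lib, design)
    bands = variability_bands(silc_qc_table(ann, design, lib))
    records = compute_stability(ann, design, bands["mav"].to_dict(), library=lib)
    ext = extreme_records(records, design)
    calls = ext.set_index("metabolite")["call"]

    correct = sum(calls.get(m) == "increased" for m in up) + sum(
        calls.get(m) == "decreased" for m in down
    )
    nulls = [m for m in mets if m not in up and m not in down]
    false_flags = sum(calls.get(m) in ("increased", "decreased") for m in nulls)
    return {
        "sensitivity": correct / max(len(drifters), 1),
        "false_flag_rate": false_flags / max(len(nulls), 1),
        "n_drifters": len(drifters),
        "n_null": len(nulls),
        "band_mav": float(bands.loc[series, "mav"]),
    }


def aggregate_recovery(seeds: list[int], **kwargs) -> dict[str, float]:
    """Mean sensitivity and false-flag rate over several generator seeds."""
    runs = [drifter_recovery_experiment(seed=s, **kwargs) for s in seeds]
    return {
        "sensitivity": float(np.mean([r["sensitivity"] for r in runs])),
        "false_flag_rate": float(np.mean([r["false_flag_rate"] for r in runs])),
        "n_seeds": len(seeds),
        "n_drifters": runs[0]["n_drifters"],
        "n_null": runs[0]["n_null"],
    }


def null_battery_experiment(
    seed: int,
    n_metabolites: int = 150,
    n_silc: int = 10,
    noise_sigma: float = 0.05,
    pools: int = 3,
    replicates: int = 3,
    grid: Mapping[str, list[float]] | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Global-null run (no injected drift): affected counts and the fraction
    of features Bonferroni-significant under RM-ANOVA and Kruskal-Wallis."""
    if grid is None:
        grid = {"freeze_thaw": [1, 2, 3, 4, 5, 6, 7]}
    lib = generate_library(n_metabolites + n_silc, (70, 600), n_silc, seed=seed)
    design = generate_design(pools, grid, replicates)
    eff = EffectSpec(noise_sigma=noise_sigma, seed=seed + 2)
    peaks = simulate_peak_tables(lib, design, eff)
    ann = summed_intensities(match_peaks(peaks, lib), lib, design)
    bands = variability_bands(silc_qc_table(ann, design, lib))
    records = compute_stability(ann, design, bands["mav"].to_dict(), library=lib)
    counts = count_affected(extreme_records(records, design))

    frames = [feature_tests(ann, design, s) for s in design.condition_series()]
    tests = pd.concat(frames, ignore_index=True)
    out = {"n_affected": int(counts["n_total_affected"].sum())}
    for name in ("rm_anova", "kruskal_wallis"):
        sub = tests[tests["test"] == name]
        out[f"{name}_significant_fraction"] = float(
            (sub["p_bonferroni"] < alpha).mean()
        )
    return out
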