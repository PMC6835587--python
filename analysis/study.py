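"""Shared definition of the emulated storage-stability study.

The synthetic study mirrors the design of the CSF stability experiment:
3 CSF pools x (1 reference + 22 storage conditions) x 3 infusion
replicates, a mass library carrying the neurometabolic panel plus 17
spike-in sILC channels, lognormal technical noise calibrated so the CV of
triplicate-averaged sILC intensities across samples is ~0.166 (the scale
of the published run), four excluded samples mimicking hampered infusions, and a
handful of injected storage effects shaped like the instabilities the
assay is meant to find (a purine degrading over freeze/thaw cycles, an
amino acid accumulating, a labile folate decaying at -20 degC, organic
acids decaying in the cold and at room temperature).
"""

from pathlib import Path

import dims_stability as ds
from dims_stability import datasets

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

# per-infusion log-noise; after triplicate averaging the sample-level sILC
# CV is ~ sqrt(exp(sigma^2 / 3) - 1) ~= 0.166
NOISE_SIGMA = 0.285

#: Injected ground-truth storage effects (level -> true fold change).
TRUE_DRIFTS = {
    "Adenine": {
        "freeze_thaw": {5: 0.7, 6: 0.55, 7: 0.45},
        "room": {72: 1.6, 168: 2.1},
    },
    "Glycine": {"freeze_thaw": {6: 3.5, 7: 5.2}},
    "5-Methyltetrahydrofolic acid": {"minus20": {3: 0.65, 4: 0.5}},
    "Cis-Aconitic acid": {
        "fridge": {72: 0.7, 168: 0.5},
        "room": {24: 0.75, 48: 0.6, 72: 0.5, 168: 0.35},
    },
    "Pyruvic acid": {"fridge": {168: 0.6}, "room": {72: 0.65, 168: 0.5}},
    "Orotic acid": {"fridge": {72: 1.45, 168: 1.8}},
}

#: Samples whose infusion "failed": dropped from every analysis (65/69 kept).
EXCLUDED_SAMPLES = [
    "P2_freeze_thaw_1",
    "P1_freeze_thaw_7",
    "P3_fridge_168",
    "P3_room_2",
]


def build_study(seed: int = 1):
    library = datasets.synthetic_reference_library(n_filler=80, seed=seed + 20_000)
    design = ds.generate_design(3, None, 3).exclude(EXCLUDED_SAMPLES)
    effects = ds.EffectSpec(
        drifts=TRUE_DRIFTS,
        pool_factors=(1.0, 1.15, 0.9),
        noise_sigma=NOISE_SIGMA,
        seed=seed,
    )
    return library, design, effects


def load_annotated(library=None, design=None):
    """Re-load the annotated matrix written by the earlier analysis steps."""
    import pandas as pd

    if library is None:
        library = ds.MetaboliteLibrary.from_tsv(RESULTS / "library.tsv")
    if design is None:
        design = ds.StudyDesign.from_tsv(RESULTS / "design.tsv")
    peaks = pd.read_csv(RESULTS / "peaks.csv")
    matches = ds.match_peaks(peaks, library)
    return library, design, ds.summed_intensities(matches, library, design)
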