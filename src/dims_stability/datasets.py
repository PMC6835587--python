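"""Bundled reference data for the CSF storage-stability analysis.

Three small datasets ship with the package:

* ``silc_reference_table`` — per-compound CV and extreme-condition median
  absolute variation for the 17 stable-isotope-labelled spike-ins of a
  published CSF storage-stability run (freeze/thaw cycle 7; -20 degC for
  4 months; 5-8 degC and 18-22 degC for 168 h).  These printed values are
  inputs for summary-level reproduction checks.
* ``neuro_panel`` — the neurometabolic-diagnostics panel: metabolite
  annotation names with their group labels (amino acids, neurotransmitters,
  purines/pyrimidines, organic acids, creatine metabolism, vitamers,
  pterines, vitamin B6 vitamers, methyl donors, other).  As printed the
  group lists contain 108 entries for 106 m/z peaks (glutamic acid is listed
  under two groups); duplicates are dropped on request.
* ``synthetic_reference_library`` — a fixture mass library combining the
  panel names, 17 sILC channels and unnamed filler metabolites.  The masses
  are SYNTHETIC stand-ins drawn deterministically (real monoisotopic masses
  of the panel compounds are not bundled); use it for end-to-end exercises,
  not for annotating real spectra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library import MetaboliteLibrary, generate_library

#: Condition-series keys used across the package, in study order.
SERIES_ORDER = ("freeze_thaw", "minus20", "fridge", "room")

# (compound, cv, mav freeze/thaw 7, mav -20C 4 mo, mav 5-8C 168 h, mav 18-22C 168 h)
_SILC_ROWS = [
    ("15N;2-13C-glycine", 0.580, 0.975, 1.732, 6.999, 1.855),
    ("2H4-alanine", 0.161, 0.371, 0.070, 0.171, 0.188),
    ("2H3-leucine", 0.166, 0.411, 0.037, 0.158, 0.265),
    ("2H3-methionine", 0.775, 3.388, 0.188, 0.607, 0.359),
    ("13C6-phenylalanine", 0.149, 0.374, 0.050, 0.142, 0.204),
    ("13C6-tyrosine", 0.150, 0.349, 0.043, 0.098, 0.206),
    ("2H3-aspartate", 0.160, 0.349, 0.137, 0.110, 0.155),
    ("2H3-glutamate", 0.126, 0.247, 0.099, 0.110, 0.074),
    ("2H2-ornithine", 0.183, 0.540, 0.014, 0.108, 0.168),
    ("2H2-citrulline", 0.134, 0.231, 0.070, 0.131, 0.038),
    ("2H4;13C-arginine", 0.163, 0.380, 0.105, 0.190, 0.170),
    ("2H8-valine", 0.155, 0.377, 0.042, 0.124, 0.222),
    ("2H9-carnitine", 0.202, 0.580, 0.072, 0.179, 0.162),
    ("2H3-acetylcarnitine", 1.058, 432.707, 689.785, 0.567, 0.999),
    ("2H3-propionylcarnitine", 0.194, 0.384, 0.038, 0.225, 0.161),
    ("2H3-butyrylcarnitine", 2.914, 42.155, 0.164, 92.851, 0.277),
    ("2H9-isovalerylcarnitine", 0.217, 0.519, 0.103, 0.215, 0.173),
]


def silc_reference_table() -> pd.DataFrame:
    """The 17-compound spike-in QC reference table (CV and per-series MAV)."""
    return pd.DataFrame(
        _SILC_ROWS,
        columns=["compound", "cv"] + [f"mav_{s}" for s in SERIES_ORDER],
    ).set_index("compound")


_PANEL = {
    "amino acids": [
        "Alanine", "Arginine", "Asparagine", "Aspartic acid", "Cysteine",
        "Cystine", "Glutamic acid", "Glutamine", "Glycine", "Histidine",
        "Homoarginine", "Homocarnosine", "(Iso)leucine", "Lysine",
        "Methionine", "Phenylalanine", "Proline", "Serine", "Threonine",
        "Tryptophan", "Tyrosine", "Ornithine", "Taurine", "Valine",
    ],
    "neurotransmitters": [
        "3-Methoxytyrosine/3-OMD/Methyldopa", "5-Hydroxyindoleacetic acid",
        "5-Hydroxytryptophan", "5-Methyltetrahydrofolic acid", "Dopamine",
        "Dopamine 4-sulfate", "Dopamine glucuronide", "Epinephrine",
        "Epinephrine glucuronide", "Homovanillic acid/3-OH-phenyllactic acid",
        "Epinephrine sulfate", "Gamma-aminobutyric acid", "Glutamic acid",
        "l-Dopa/Dihydroxyphenylalanine", "Methoxyhydroxyphenylglycol",
        "n-Acetylserotonin", "Norepinephrine", "Norepinephrine sulfate",
        "Serotonin", "Vanillactic acid", "Vanillylmandelic acid",
    ],
    "purines, pyrimidines": [
        "5-Hydroxymethyluracil", "Adenine", "Adenosine/Deoxyguanosine",
        "AICAR", "Deoxyadenosine", "Deoxyinosine", "Dihydrothymine",
        "Dihydrouracil", "Guanosine", "Hypoxanthine", "Inosine",
        "Orotic acid", "SAICAR", "Succinyladenosine", "Thymidine",
        "Thymine", "Uracil", "Uric acid", "Uridine", "Xanthine",
    ],
    "organic acids": [
        "n-Acetylaspartylglutamic acid", "2-Methylcitric acid",
        "3-Hydroxybutyric acid", "3-Hydroxyisovaleric acid",
        "4-Guanidinobutanoic acid", "Acetoacetic acid", "Cis-Aconitic acid",
        "Citric acid", "Fumaric acid", "Lactic acid/3-OH-propionic acid",
        "Malic acid", "n-Acetylaspartic acid", "Oxalacetic acid",
        "Propionic acid", "Pyruvic acid", "Succinic acid/Methylmalonic acid",
    ],
    "creatine metabolism": [
        "Creatine", "Creatinine", "Guanidoacetic acid", "Phosphocreatine",
        "Phosphocreatinine",
    ],
    "vitamers": [
        "Folic acid", "Thiamine", "Thiamine monophosphate",
        "Thiamine pyrophosphate", "Thiamine triphosphate",
    ],
    "pterines": [
        "7,8-Dihydroneopterin", "Dihydrobiopterin", "Neopterin",
        "Biopterin/Sepiapterin/Primapterin/6-Pyruvoyl-tetrahydropterin",
        "Tetrahydroneopterin", "Tetrahydrobiopterin",
    ],
    "vitamin B6 vitamers": [
        "Pipecolic acid", "Pyridoxal", "Pyridoxal 5'-phosphate",
        "Pyridoxamine", "Pyridoxamine 5'-phosphate", "Pyridoxine",
        "Pyridoxine 5'-phosphate",
        "Alpha-aminoadipic acid delta-semialdehyde",
    ],
    "other": ["Saccharopine"],
    "methyl donor": ["s-Adenosylhomocysteine", "s-Adenosylmethionine"],
}


def neuro_panel(deduplicate: bool = True) -> pd.DataFrame:
    """Neurometabolic panel names with group labels.

    With ``deduplicate`` (default) names listed under more than one group
    keep their first group only, giving one row per m/z annotation.
    """
    rows = [(name, group) for group, names in _PANEL.items() for name in names]
    df = pd.DataFrame(rows, columns=["name", "group"])
    if deduplicate:
        df = df.drop_duplicates("name", keep="first").reset_index(drop=True)
    return df


def synthetic_reference_library(
    n_filler: int = 30, seed: int = 20191018
) -> MetaboliteLibrary:
    """Fixture library: panel + sILC + filler entries with SYNTHETIC masses.

    Masses are drawn deterministically with pairwise separation > 4 ppm; the
    panel and sILC names are real annotation labels but their masses here are
    stand-ins, so this library is for pipeline exercises only.
    """
    panel = neuro_panel()
    silc = silc_reference_table().index.tolist()
    n_total = len(panel) + len(silc) + n_filler
    base = generate_library(n_total, (70.0, 600.0), 0, seed=seed)
    masses = base.entries["monoisotopic_mass"].to_numpy()
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_total)

    names, groups, in_panel, is_silc = [], [], [], []
    idx = 0
    for name, group in panel.itertuples(index=False):
        names.append(name); groups.append(group); in_panel.append(True); is_silc.append(False)
        idx += 1
    for name in silc:
        names.append(name); groups.append("silc"); in_panel.append(False); is_silc.append(True)
        idx += 1
    for i in range(n_filler):
        names.append(f"unknown_{i + 1:03d}"); groups.append(""); in_panel.append(False)
        is_silc.append(False)
    df = pd.DataFrame(
        {
            "name": names,
            "monoisotopic_mass": masses[order],
            "group": groups,
            "in_neuro_panel": in_panel,
            "is_silc": is_silc,
        }
    )
    return MetaboliteLibrary(df)
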