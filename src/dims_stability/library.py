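"""Metabolite mass library: names, monoisotopic masses, group labels, flags.

The library is the annotation target list.  Any mass list can be used (the
format does not assume a particular database); entries carry an optional
group label, a neurometabolic-panel membership flag and a flag marking
stable-isotope-labelled spike-in compounds (sILC) used for QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adducts import DEFAULT_ADDUCTS, SCAN_WINDOW, AdductRule

REQUIRED_COLUMNS = ("name", "monoisotopic_mass", "group", "in_neuro_panel", "is_silc")


@dataclass
class MetaboliteLibrary:
    """Table of annotation targets.

    ``entries`` columns: ``name`` (unique), ``monoisotopic_mass`` (Da, > 0),
    ``group`` (label or empty), ``in_neuro_panel`` (bool), ``is_silc`` (bool)
    and a derived ``reachable`` flag — whether at least one adduct channel of
    the entry lands inside the instrument scan window.
    """

    entries: pd.DataFrame = field(default_factory=lambda: _empty_entries())

    def __post_init__(self) -> None:
        df = self.entries.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"library missing columns: {missing}")
        if len(df):
            if (df["monoisotopic_mass"] <= 0).any():
                bad = df.loc[df["monoisotopic_mass"] <= 0, "name"].tolist()
                raise ValueError(f"non-positive monoisotopic mass for {bad}")
            if df["name"].duplicated().any():
                dup = df.loc[df["name"].duplicated(), "name"].tolist()
                raise ValueError(f"duplicate metabolite names: {dup}")
        df["in_neuro_panel"] = df["in_neuro_panel"].astype(bool)
        df["is_silc"] = df["is_silc"].astype(bool)
        df["reachable"] = _reachable(df["monoisotopic_mass"].to_numpy(float))
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return self.entries["name"].tolist()

    @property
    def silc_names(self) -> list[str]:
        return self.entries.loc[self.entries["is_silc"], "name"].tolist()

    @property
    def panel_names(self) -> list[str]:
        return self.entries.loc[self.entries["in_neuro_panel"], "name"].tolist()

    def masses(self) -> pd.Series:
        return self.entries.set_index("name")["monoisotopic_mass"]

    def to_tsv(self, path: str | Path) -> None:
        self.entries.drop(columns=["reachable"]).to_csv(
            path, sep="\t", index=False, float_format="%.9f"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaboliteLibrary":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        df["group"] = df["group"].fillna("")
        return cls(df)


def _empty_entries() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": pd.Series(dtype=str),
            "monoisotopic_mass": pd.Series(dtype=float),
            "group": pd.Series(dtype=str),
            "in_neuro_panel": pd.Series(dtype=bool),
            "is_silc": pd.Series(dtype=bool),
        }
    )


def _reachable(
    masses: np.ndarray,
    adducts: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    window: tuple[float, float] = SCAN_WINDOW,
) -> np.ndarray:
    lo, hi = window
    if masses.size == 0:
        return np.zeros(0, dtype=bool)
    shifted = masses[:, None] + np.array([a.mass_shift for a in adducts])[None, :]
    return ((shifted >= lo) & (shifted <= hi)).any(axis=1)


def generate_library(
    n_metabolites: int,
    mass_range: tuple[float, float] = (70.0, 600.0),
    n_silc: int = 0,
    *,
    seed: int,
    min_separation_ppm: float = 4.0,
) -> MetaboliteLibrary:
    """Draw a random library with pairwise well-separated masses.

    Masses are drawn uniformly over ``mass_range``; a candidate closer than
    ``min_separation_ppm`` (relative to the smaller mass) to an accepted mass
    is rejected, so with the default of twice the 2 ppm matching tolerance
    every synthetic peak maps back to a unique metabolite.  ``n_silc`` entries
    are flagged as stable-isotope-labelled spike-ins.  Deterministic for a
    fixed seed.
    """
    if n_metabolites < 0:
        raise ValueError("n_metabolites must be >= 0")
    if n_silc < 0 or n_silc > n_metabolites:
        raise ValueError("n_silc must be between 0 and n_metabolites")
    lo, hi = mass_range
    if not (lo < hi):
        raise ValueError("empty mass range")
    if lo <= 50.0 or hi > 600.0:
        raise ValueError("mass range must lie within (50, 600] Da")

    rng = np.random.default_rng(seed)
    accepted: list[float] = []
    attempts = 0
    max_attempts = max(1000, 200 * max(n_metabolites, 1))
    while len(accepted) < n_metabolites:
        if attempts > max_attempts:
            raise RuntimeError("could not place masses with requested separation")
        attempts += 1
        m = float(rng.uniform(lo, hi))
        ok = True
        for a in accepted:
            small = min(a, m)
            if abs(a - m) / small * 1e6 <= min_separation_ppm:
                ok = False
                break
        if ok:
            accepted.append(m)

    masses = np.array(accepted)
    is_silc = np.zeros(n_metabolites, dtype=bool)
    if n_silc:
        is_silc[rng.choice(n_metabolites, size=n_silc, replace=False)] = True
    names = []
    i_met = i_silc = 0
    for flag in is_silc:
        if flag:
            i_silc += 1
            names.append(f"silc_{i_silc:02d}")
        else:
            i_met += 1
            names.append(f"met_{i_met:04d}")
    df = pd.DataFrame(
        {
            "name": names,
            "monoisotopic_mass": masses,
            "group": np.where(is_silc, "silc", ""),
            "in_neuro_panel": False,
            "is_silc": is_silc,
        }
    )
    return MetaboliteLibrary(df)
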