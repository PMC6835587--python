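"""Singly-charged adduct rules for direct-infusion MS annotation.

Five ion-formation channels are considered per neutral metabolite:
protonation/deprotonation ([M+H]+, [M-H]-) and the single adducts
[M+Na]+, [M+K]+ and [M+Cl]-.  Mass shifts are monoisotopic and include
the electron mass, so [M+H]+ is M + 1.007276 Da, not M + 1.007825 Da.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AdductRule:
    """One ion-formation channel: label, signed mass shift (Da), polarity."""

    label: str
    mass_shift: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


#: Default channel set; singly charged species only.
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", +1.007276, "positive"),
    AdductRule("[M-H]-", -1.007276, "negative"),
    AdductRule("[M+Na]+", +22.989222, "positive"),
    AdductRule("[M+K]+", +38.963158, "positive"),
    AdductRule("[M+Cl]-", +34.969401, "negative"),
)

ADDUCTS_BY_LABEL: dict[str, AdductRule] = {a.label: a for a in DEFAULT_ADDUCTS}

#: Instrument scan window in m/z; peaks and theoretical channels outside are ignored.
SCAN_WINDOW: tuple[float, float] = (70.0, 600.0)


def compute_adduct_mz(monoisotopic_mass: float, adduct: AdductRule | str) -> float:
    """Theoretical m/z of a neutral mass in one adduct channel.

    Parameters
    ----------
    monoisotopic_mass
        Neutral monoisotopic mass in Da; must be positive.
    adduct
        An :class:`AdductRule` or one of the default labels.
    """
    if monoisotopic_mass <= 0:
        raise ValueError("monoisotopic mass must be positive")
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS_BY_LABEL[adduct]
        except KeyError:
            raise KeyError(f"unknown adduct label {adduct!r}") from None
    return monoisotopic_mass + adduct.mass_shift


def reachable_in_window(
    monoisotopic_mass: float,
    adducts: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    window: tuple[float, float] = SCAN_WINDOW,
) -> bool:
    """True if at least one adduct channel falls inside the scan window."""
    lo, hi = window
    return any(lo <= monoisotopic_mass + a.mass_shift <= hi for a in adducts)
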