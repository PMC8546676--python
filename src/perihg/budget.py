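"""Mercury speciation and biomass bookkeeping.

Arithmetic on measured Hg pools: inorganic Hg by subtraction (IHg = THg -
MMHg), the MMHg share of total Hg, the organic-matter fraction of periphyton
biomass (AFDW/DW), and the fold-ratio of an isotope spike over ambient
concentrations.  Water concentrations are ng/L; periphyton concentrations
ng/g dry weight.  Computation is at full precision; rounding (one decimal)
is presentation-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "SpeciationMeasurement",
    "BiomassMeasurement",
    "ihg_by_subtraction",
    "percent_mmhg",
    "afdw_fraction",
    "spike_fold_ratio",
]


@dataclass(frozen=True)
class SpeciationMeasurement:
    """MMHg / THg / IHg concentrations for one site and matrix.

    At least two of the three pools must be present; THg is reconstructed
    as MMHg + IHg where absent.
    """

    site_id: str
    matrix: Literal["water", "periphyton"]
    mmhg: float | None = None
    thg: float | None = None
    ihg: float | None = None

    def __post_init__(self) -> None:
        present = [v for v in (self.mmhg, self.thg, self.ihg) if v is not None]
        if len(present) < 2:
            raise ValueError("need at least two of mmhg/thg/ihg")
        if any(v < 0 for v in present):
            raise ValueError("concentrations must be non-negative")
        if self.thg is not None and self.mmhg is not None and self.thg < self.mmhg:
            raise ValueError("THg cannot be below MMHg")

    def total(self) -> float:
        """THg, reconstructed as MMHg + IHg when not measured directly."""
        if self.thg is not None:
            return self.thg
        return self.mmhg + self.ihg  # both present by the invariant


@dataclass(frozen=True)
class BiomassMeasurement:
    """Dry weight and ash-free dry weight of a periphyton sample (mg)."""

    dw: float
    afdw: float

    def __post_init__(self) -> None:
        if not 0 <= self.afdw <= self.dw:
            raise ValueError("need 0 <= AFDW <= DW")


def ihg_by_subtraction(m: SpeciationMeasurement) -> SpeciationMeasurement:
    """Fill in IHg = THg - MMHg.

    An already-present IHg inconsistent with the subtraction (beyond 1e-9)
    is overwritten with a warning.
    """
    if m.mmhg is None or m.thg is None:
        raise ValueError("ihg_by_subtraction needs both mmhg and thg")
    if m.mmhg > m.thg:
        raise ValueError("MMHg exceeds THg: negative IHg impossible")
    ihg = m.thg - m.mmhg
    if m.ihg is not None and abs(m.ihg - ihg) > 1e-9:
        warnings.warn(
            f"site {m.site_id}: stored IHg {m.ihg} inconsistent with "
            f"THg - MMHg = {ihg}; overwritten",
            stacklevel=2,
        )
    return replace(m, ihg=ihg)


def percent_mmhg(m: SpeciationMeasurement) -> float:
    """MMHg as a percentage of total Hg."""
    if m.mmhg is None:
        raise ValueError("percent_mmhg needs mmhg")
    thg = m.total()
    if thg == 0:
        raise ValueError("THg is zero; percentage undefined")
    return 100.0 * m.mmhg / thg


def afdw_fraction(b: BiomassMeasurement) -> float:
    """Ash-free dry weight as a percentage of dry weight."""
    if b.dw <= 0:
        raise ValueError("dry weight must be positive")
    return 100.0 * b.afdw / b.dw


def spike_fold_ratio(
    spike_conc: float,
    ambient: list[SpeciationMeasurement],
    species: Literal["mmhg", "thg"] = "thg",
) -> float:
    """Spike concentration over the across-site mean ambient concentration.

    ``species`` selects MMHg or THg; THg is reconstructed per measurement
    when not directly present.
    """
    if not ambient:
        raise ValueError("no ambient measurements")
    if species == "thg":
        values = [m.total() for m in ambient]
    elif species == "mmhg":
        values = [m.mmhg for m in ambient]
        if any(v is None for v in values):
            raise ValueError("an ambient measurement lacks mmhg")
    else:
        raise ValueError(f"unknown species {species!r}")
    mean = sum(values) / len(values)
    if mean == 0:
        raise ValueError("mean ambient concentration is zero")
    return spike_conc / mean
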