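"""Acetylene-reduction and 15N2-fixation rates across physiological scales.

The 15N2 assay incubates whole plants in 80% air : 20% 15N2 and measures
the 15N atom percent and total N of the shoot, root and nodule fractions.
The isotopic signal is the atom percent excess (APE), the measured atom%
minus the 15N natural abundance (0.36782%).  Fixed N per fraction is

    N2 fixed = (APE / 100) · total N · 1/(4 · gas fraction)

which is the published "×5/4" factor at the standard 20% gas fraction
(``literal`` mode); ``strict`` mode additionally divides by the incubation
time so that each correction is applied exactly once and auditably.
Fraction values are summed per plant, and optionally converted to µmol N2
(molar mass 28.0134 g/mol).

``normalize_rate`` expresses a per-plant rate across the eight scales used
to compare hosts: per plant, per g shoot dry weight, per nodule volume, per
nodule dry mass, per infected volume, per bacteroid, per pg bacteroid
protein, and per µm³ bacteroid volume.  The last three form an exact
cascade: per_bacteroid = per_bacteroid_volume × mean volume and
per_bacteroid_protein = per_bacteroid / mean protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .units import (AMOL_PER_UMOL, N15_NATURAL_ABUNDANCE, N2_MOLAR_MASS,
                    NMOL_PER_UMOL)

__all__ = [
    "IsotopeMeasurement",
    "RateDenominators",
    "RateScaleTable",
    "ape",
    "n2_fixed_per_fraction",
    "plant_fixation_rate",
    "ara_rate",
    "normalize_rate",
]


@dataclass(frozen=True)
class IsotopeMeasurement:
    """15N enrichment of one plant fraction (shoot, root or nodule)."""

    fraction: str
    atom_percent_15n: float
    total_n_ug: float
    incubation_h: float = 2.0
    gas_fraction_15n2: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_percent_15n <= 100.0:
            raise ValueError("atom percent must lie in [0, 100]")
        if self.total_n_ug < 0:
            raise ValueError("total N must be non-negative")
        if not 0.0 < self.gas_fraction_15n2 <= 1.0:
            raise ValueError("gas fraction must lie in (0, 1]")
        if self.incubation_h <= 0:
            raise ValueError("incubation time must be positive")


def ape(atom_percent: float) -> float:
    """Atom percent excess: measured atom% minus natural abundance.

    Values below natural abundance are floored at zero with a warning
    (they indicate measurement noise, not negative fixation).
    """
    if atom_percent < 0:
        raise ValueError("atom percent must be non-negative")
    excess = atom_percent - N15_NATURAL_ABUNDANCE
    if excess < 0:
        warnings.warn("atom percent below natural abundance; APE floored at 0",
                      stacklevel=2)
        return 0.0
    return excess


def n2_fixed_per_fraction(m: IsotopeMeasurement, mode: str = "literal") -> float:
    """µg N2 fixed per hour by one plant fraction.

    ``literal`` applies the published factor 1/(4·gas_fraction) (= 5/4 at
    20% gas); ``strict`` additionally divides by the incubation time.
    """
    excess = ape(m.atom_percent_15n)
    factor = 1.0 / (4.0 * m.gas_fraction_15n2)
    value = (excess / 100.0) * m.total_n_ug * factor
    if mode == "literal":
        return value
    if mode == "strict":
        return value / m.incubation_h
    raise ValueError(f"unknown mode {mode!r}")


def plant_fixation_rate(fractions: list[IsotopeMeasurement], molar: bool = True,
                        mode: str = "literal") -> float:
    """Whole-plant fixation rate: sum of fraction rates.

    Returns µmol N2/h/plant when ``molar`` (µg N2 divided by 28.0134),
    else µg N2/h/plant.
    """
    if not fractions:
        raise ValueError("need at least one plant fraction")
    labels = [m.fraction for m in fractions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate fraction labels: {labels}")
    total_ug = sum(n2_fixed_per_fraction(m, mode) for m in fractions)
    return total_ug / N2_MOLAR_MASS if molar else total_ug


def ara_rate(ethylene_nmol: float, incubation_h: float = 1.0) -> float:
    """Acetylene-reduction rate, µmol C2H4/h, from an ethylene amount."""
    if incubation_h <= 0:
        raise ValueError("incubation time must be positive")
    if ethylene_nmol < 0:
        raise ValueError("ethylene amount must be non-negative")
    return (ethylene_nmol / NMOL_PER_UMOL) / incubation_h


@dataclass(frozen=True)
class RateDenominators:
    """Per-plant denominators for the eight-scale normalization.

    ``bacteroid_protein_pg`` and ``bacteroid_volume_um3`` are single-
    bacteroid means, so the bacteroid-level scales form an exact cascade.
    """

    sdw_g: float
    nodule_volume_cm3: float
    nodule_dry_mass_mg: float
    infected_volume_mm3: float
    bacteroid_count: float
    bacteroid_protein_pg: float
    bacteroid_volume_um3: float

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"denominator {name} must be positive")


@dataclass(frozen=True)
class RateScaleTable:
    """One physiological rate expressed across all eight scales."""

    per_plant: float               # µmol/h
    per_g_sdw: float               # µmol/h/g
    per_nodule_volume: float       # µmol/h/cm³
    per_nodule_dry_mass: float     # nmol/h/mg
    per_infected_volume: float     # nmol/h/mm³
    per_bacteroid: float           # amol/h
    per_bacteroid_protein: float   # amol/h/pg
    per_bacteroid_volume: float    # amol/h/µm³


def normalize_rate(rate_per_plant_umol_h: float,
                   d: RateDenominators) -> RateScaleTable:
    """Express a per-plant rate (µmol/h) at every physiological scale."""
    if rate_per_plant_umol_h < 0:
        raise ValueError("rate must be non-negative")
    r = rate_per_plant_umol_h
    per_bacteroid = r * AMOL_PER_UMOL / d.bacteroid_count
    return RateScaleTable(
        per_plant=r,
        per_g_sdw=r / d.sdw_g,
        per_nodule_volume=r / d.nodule_volume_cm3,
        per_nodule_dry_mass=r * NMOL_PER_UMOL / d.nodule_dry_mass_mg,
        per_infected_volume=r * NMOL_PER_UMOL / d.infected_volume_mm3,
        per_bacteroid=per_bacteroid,
        per_bacteroid_protein=per_bacteroid / d.bacteroid_protein_pg,
        per_bacteroid_volume=per_bacteroid / d.bacteroid_volume_um3,
    )
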