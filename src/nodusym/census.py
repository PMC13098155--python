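"""Bacteroid census: 3-D morphology summaries, packing fractions and counts.

Per-bacteroid volumes and surface areas come from manual segmentation of
serial block-face SEM stacks; packing fractions from exhaustively segmented
subvolumes of infected plant cells.  Combining the packing fraction with the
infected nodule volume gives the total bacteroid volume per nodule, and
dividing by the mean single-bacteroid volume gives the bacteroid count.

Flow-cytometry enumeration applies the three gates used for fluorescently
tagged bacteroid suspensions: forward scatter > 0, side-scatter aspect
ratio > 0.4 ("singlets"), and fluorescence > 3,000 FI ("yellow"); all gates
are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import UM3_PER_MM3

__all__ = [
    "MorphologySummary",
    "summarize_morphology",
    "validate_segmentation",
    "packing_fraction",
    "total_bacteroid_volume",
    "bacteroids_per_nodule",
    "protein_density",
    "count_bacteroids_flow",
    "census_summary",
]

#: default flow-cytometry gate thresholds (strict inequalities)
FSC_GATE = 0.0
ASPECT_GATE = 0.4
YELLOW_GATE = 3000.0


@dataclass(frozen=True)
class MorphologySummary:
    """Cohort means ± SE of bacteroid volume, surface area and SA:V."""

    mean_volume: float       # µm³
    se_volume: float
    mean_surface: float      # µm²
    se_surface: float
    mean_sa_v: float         # 1/µm, mean of per-bacteroid ratios
    se_sa_v: float
    n: int


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    se = x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
    return float(x.mean()), float(se)


def summarize_morphology(volumes, surfaces) -> MorphologySummary:
    """Mean volume, surface area, and SA:V ratio of a bacteroid cohort.

    SA:V is the mean of per-bacteroid ratios, not the ratio of means —
    the two differ for heterogeneous cohorts and the per-bacteroid
    convention is the one the summary statistics of this pipeline use.
    """
    volumes = np.asarray(volumes, dtype=float)
    surfaces = np.asarray(surfaces, dtype=float)
    if volumes.size == 0 or volumes.size != surfaces.size:
        raise ValueError("need equal-length, non-empty volume and surface arrays")
    mv, sev = _mean_se(volumes)
    ms, ses = _mean_se(surfaces)
    ratios = surfaces / volumes
    mr, ser = _mean_se(ratios)
    return MorphologySummary(mv, sev, ms, ses, mr, ser, int(volumes.size))


def validate_segmentation(df: pd.DataFrame) -> pd.DataFrame:
    """Check a segmentation table for physical consistency.

    Requires positive volumes/surface areas and the isoperimetric
    inequality SA³ >= 36π V² (no closed surface can beat a sphere).
    """
    if not (df["volume_um3"] > 0).all() or not (df["surface_um2"] > 0).all():
        raise ValueError("volumes and surface areas must be positive")
    bad = df["surface_um2"] ** 3 < 36.0 * math.pi * df["volume_um3"] ** 2 * (1 - 1e-9)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} record(s) violate the isoperimetric inequality")
    return df


def packing_fraction(samples: pd.DataFrame) -> tuple[float, float]:
    """Mean (± SE) fraction of subvolume occupied by bacteroids.

    ``samples`` needs columns X_um, Y_um, Z_um, occupied_um3; each row is an
    exhaustively segmented subvolume (conventionally 8 × 8 × 2 µm).
    """
    if len(samples) == 0:
        raise ValueError("need at least one packing sample")
    total = samples["X_um"] * samples["Y_um"] * samples["Z_um"]
    if (samples["occupied_um3"] > total * (1 + 1e-9)).any():
        raise ValueError("occupied volume exceeds subvolume")
    fractions = (samples["occupied_um3"] / total).to_numpy(dtype=float)
    return _mean_se(fractions)


def total_bacteroid_volume(v_i_mm3: float, packing: float) -> float:
    """Total bacteroid volume per nodule (mm³) = infected volume × packing."""
    if not 0.0 <= packing <= 1.0:
        raise ValueError("packing fraction must lie in [0, 1]")
    if v_i_mm3 < 0:
        raise ValueError("infected volume must be non-negative")
    return v_i_mm3 * packing


def bacteroids_per_nodule(total_volume_mm3: float, mean_volume_um3: float) -> float:
    """Bacteroid count per nodule from total (mm³) and mean (µm³) volume."""
    if mean_volume_um3 <= 0:
        raise ValueError("mean bacteroid volume must be positive")
    if total_volume_mm3 <= 0:
        raise ValueError("total bacteroid volume must be positive")
    return total_volume_mm3 * UM3_PER_MM3 / mean_volume_um3


def protein_density(protein_per_bacteroid_pg: float, mean_volume_um3: float) -> float:
    """Protein density (pg/µm³) of a single bacteroid."""
    if mean_volume_um3 <= 0:
        raise ValueError("mean bacteroid volume must be positive")
    if protein_per_bacteroid_pg <= 0:
        raise ValueError("protein per bacteroid must be positive")
    return protein_per_bacteroid_pg / mean_volume_um3


def count_bacteroids_flow(events: pd.DataFrame, volume_analyzed_ul: float,
                          fsc_col: str = "FSC",
                          aspect_col: str = "SSC_aspect_ratio",
                          fluor_col: str = "YFP_FI") -> float:
    """Yellow-gated event concentration (events/ml) from a flow-event table.

    Gates (all strict): FSC > 0; SSC aspect ratio > 0.4 (singlets);
    fluorescence > 3,000 FI (yellow).  An event sitting exactly on a gate
    boundary is excluded.
    """
    for col in (fsc_col, aspect_col, fluor_col):
        if col not in events.columns:
            raise ValueError(f"flow-event table missing column {col!r}")
    if volume_analyzed_ul <= 0:
        raise ValueError("analyzed volume must be positive")
    gated = events[(events[fsc_col] > FSC_GATE)
                   & (events[aspect_col] > ASPECT_GATE)
                   & (events[fluor_col] > YELLOW_GATE)]
    return len(gated) / (volume_analyzed_ul / 1.0e3)


def census_summary(segmentation: pd.DataFrame, packing_samples: pd.DataFrame,
                   v_i_mm3: float, protein_per_bacteroid_pg: float) -> dict:
    """One-stop census of a host: morphology, packing, totals, densities."""
    validate_segmentation(segmentation)
    morph = summarize_morphology(segmentation["volume_um3"],
                                 segmentation["surface_um2"])
    packing, packing_se = packing_fraction(packing_samples)
    total = total_bacteroid_volume(v_i_mm3, packing)
    count = bacteroids_per_nodule(total, morph.mean_volume)
    return {
        "mean_volume_um3": morph.mean_volume,
        "se_volume_um3": morph.se_volume,
        "mean_surface_um2": morph.mean_surface,
        "se_surface_um2": morph.se_surface,
        "mean_sa_v": morph.mean_sa_v,
        "se_sa_v": morph.se_sa_v,
        "n_bacteroids": morph.n,
        "packing_fraction": packing,
        "packing_se": packing_se,
        "total_bacteroid_volume_mm3": total,
        "bacteroids_per_nodule": count,
        "protein_per_bacteroid_pg": protein_per_bacteroid_pg,
        "protein_density_pg_um3": protein_density(protein_per_bacteroid_pg,
                                                  morph.mean_volume),
    }
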