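"""Synthetic raw-measurement tables with known ground truth.

Every raw input table of the pipeline — per-plant records, nodule-section
measurements, bacteroid segmentations, packing subvolumes, flow-cytometry
events, MaxQuant-style peptide intensities, and normalized RNA counts —
can be generated from a :class:`GroundTruth` parameter set, so downstream
stages are testable end to end and parameter recovery can be asserted.

Noise model: strictly positive measurements are lognormal with a stated
coefficient of variation (CV); counts (nodules per plant, flow events) are
Poisson.  The default parameter set encodes published cohort means with
CVs back-computed from the reported standard errors and sample sizes
(CV = SE·√n / mean).  A single top-level seed fans out to per-table child
seeds by fixed offsets, so generating one table never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .units import COPIES_PER_FMOL, N2_MOLAR_MASS, N15_NATURAL_ABUNDANCE

__all__ = [
    "Param",
    "HostTruth",
    "GroundTruth",
    "SyntheticBundle",
    "generate_plants",
    "generate_isotope_table",
    "generate_sections",
    "generate_segmentation",
    "generate_packing",
    "generate_flow_events",
    "generate_peptide_table",
    "generate_mass_fractions",
    "generate_rna_protein_pairs",
    "generate_bundle",
]

# fixed child-seed offsets per table (never reorder)
_SEED_OFFSETS = {
    "plants": 11,
    "isotope": 23,
    "sections": 37,
    "segmentation": 53,
    "packing": 67,
    "flow": 79,
    "peptides": 97,
    "rna": 113,
}


def _child_seed(seed: int, table: str) -> int:
    return (int(seed) * 131 + _SEED_OFFSETS[table]) % (2**31 - 1)


@dataclass(frozen=True)
class Param:
    """A lognormal measurement model: mean and coefficient of variation."""

    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")

    @classmethod
    def from_se(cls, mean: float, se: float, n: int) -> "Param":
        """Build from a cohort mean ± SE with known sample size."""
        return cls(mean, se * math.sqrt(n) / mean)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.cv == 0.0:
            return np.full(size, self.mean)
        sigma2 = math.log1p(self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size)


def _count(rng: np.random.Generator, p: Param, size: int) -> np.ndarray:
    """Poisson counts, degenerate to the rounded mean at zero CV."""
    if p.cv == 0.0:
        return np.full(size, round(p.mean), dtype=int)
    return rng.poisson(p.mean, size)


@dataclass(frozen=True)
class HostTruth:
    """Per-host ground-truth parameters (one legume host / strain pair)."""

    shoot_dry_mass_mg: Param
    nodule_count: Param
    plant_nodule_fresh_mass_mg: Param
    plant_nodule_dry_mass_mg: Param
    plant_nodule_volume_mm3: Param
    nodule_volume_mm3: Param
    infected_fraction: Param          # V_i / V_n, unitless
    colonization_density: Param       # f_c = A_i / A_iz, unitless
    packing_fraction: Param           # bacteroid fraction of infected cell
    bacteroid_volume_um3: Param
    bacteroid_surface_um2: Param
    protein_per_bacteroid_pg: Param
    fixation_per_plant_umol_h: Param
    ara_per_plant_umol_h: Param
    # pea-style cap geometry; ignored for spherical hosts
    cap_volume_fraction: float = 0.12
    body_aspect_ratio: float = 3.0

    def __post_init__(self) -> None:
        for name in ("infected_fraction", "colonization_density",
                     "packing_fraction"):
            p: Param = getattr(self, name)
            if not 0.0 < p.mean < 1.0:
                raise ValueError(f"{name} mean must lie in (0, 1)")

    def zero_noise(self) -> "HostTruth":
        changes = {name: Param(value.mean, 0.0)
                   for name, value in vars(self).items()
                   if isinstance(value, Param)}
        return replace(self, **changes)


#: default protein panel: per-bacteroid copy numbers (bean, pea).  Ratios
#: follow the published per-bacteroid fold changes for these enzymes;
#: absolute bean copies are order-of-magnitude realistic for a bacteroid.
DEFAULT_PANEL: dict[str, tuple[float, float]] = {
    "NifH": (60_000.0, 60_000.0 * 5.49),
    "NifD": (20_000.0, 20_000.0 * 6.42),
    "NifK": (18_000.0, 18_000.0 * 16.75),
    "FixA": (8_000.0, 8_000.0 * 4.99),
    "FixC": (3_000.0, 3_000.0 * 2.64),
    "GltA": (2_000.0, 2_000.0 * 21.19),
    "AcnA": (1_500.0, 1_500.0 * 16.86),
    "Mdh": (5_000.0, 5_000.0 * 9.44),
    "Icd": (4_000.0, 4_000.0 * 6.42),
    "GroEL": (30_000.0, 30_000.0),
}


@dataclass(frozen=True)
class GroundTruth:
    """Full two-host parameter set plus the true protein copy panel."""

    bean: HostTruth
    pea: HostTruth
    protein_copies: dict = field(
        default_factory=lambda: dict(DEFAULT_PANEL))
    seed: int = 0

    def host(self, name: str) -> HostTruth:
        if name not in ("bean", "pea"):
            raise ValueError(f"unknown host {name!r}")
        return getattr(self, name)

    def zero_noise(self) -> "GroundTruth":
        return replace(self, bean=self.bean.zero_noise(),
                       pea=self.pea.zero_noise())

    @classmethod
    def default(cls, seed: int = 0) -> "GroundTruth":
        """Published cohort means with CVs from reported SEs and n's.

        Sample sizes per measurement block: 11 plants for biomass/ARA,
        8 nodules for infection geometry, 240/246 bacteroids for
        morphology, 6 isolations for protein, 9/10 plants for 15N2.
        f_c (colonization density inside the infected zone) is not a
        published summary; 0.5 is used for both hosts.
        """
        bean = HostTruth(
            shoot_dry_mass_mg=Param.from_se(610.0, 50.2, 11),
            nodule_count=Param.from_se(125.0, 10.3, 11),
            plant_nodule_fresh_mass_mg=Param.from_se(1445.3, 94.8, 11),
            plant_nodule_dry_mass_mg=Param.from_se(81.8, 9.4, 11),
            plant_nodule_volume_mm3=Param.from_se(709.0, 43.0, 11),
            nodule_volume_mm3=Param.from_se(6.07, 0.48, 11),
            infected_fraction=Param.from_se(0.242, 0.0152, 8),
            colonization_density=Param(0.5, 0.10),
            packing_fraction=Param.from_se(0.36, 0.009, 8),
            bacteroid_volume_um3=Param.from_se(0.93, 0.02, 240),
            bacteroid_surface_um2=Param.from_se(6.73, 0.14, 240),
            protein_per_bacteroid_pg=Param.from_se(0.32, 0.02, 6),
            fixation_per_plant_umol_h=Param.from_se(1.89, 0.22, 9),
            ara_per_plant_umol_h=Param.from_se(3.31, 0.39, 11),
        )
        pea = HostTruth(
            shoot_dry_mass_mg=Param.from_se(321.0, 33.2, 11),
            nodule_count=Param.from_se(88.6, 4.18, 11),
            plant_nodule_fresh_mass_mg=Param.from_se(251.4, 13.35, 11),
            plant_nodule_dry_mass_mg=Param.from_se(17.3, 1.85, 11),
            plant_nodule_volume_mm3=Param.from_se(400.0, 6.9, 11),
            nodule_volume_mm3=Param.from_se(4.61, 0.22, 11),
            infected_fraction=Param.from_se(0.262, 0.0219, 8),
            colonization_density=Param(0.5, 0.10),
            packing_fraction=Param.from_se(0.52, 0.023, 8),
            bacteroid_volume_um3=Param.from_se(4.50, 0.09, 246),
            bacteroid_surface_um2=Param.from_se(21.1, 0.36, 246),
            protein_per_bacteroid_pg=Param.from_se(0.62, 0.03, 6),
            fixation_per_plant_umol_h=Param.from_se(0.58, 0.05, 10),
            ara_per_plant_umol_h=Param.from_se(1.92, 0.20, 11),
        )
        return cls(bean=bean, pea=pea, seed=seed)


# ---------------------------------------------------------------------------
# per-table generators


def generate_plants(gt: GroundTruth, n_plants: int, seed: int) -> pd.DataFrame:
    """Per-plant biomass, nodule counts/masses and ARA gas readings.

    One row per plant per host.  Ethylene amounts (nmol, 1 h incubation)
    invert the ARA rate so the assay stage recovers the planted rates.
    """
    if n_plants < 2:
        raise ValueError("need at least two plants per host")
    rng = np.random.default_rng(_child_seed(seed, "plants"))
    frames = []
    for host in ("bean", "pea"):
        t = gt.host(host)
        ara = t.ara_per_plant_umol_h.sample(rng, n_plants)
        frames.append(pd.DataFrame({
            "plant_id": [f"{host}_{i + 1}" for i in range(n_plants)],
            "host": host,
            "shoot_dry_mass_mg": t.shoot_dry_mass_mg.sample(rng, n_plants),
            "nodule_count": _count(rng, t.nodule_count, n_plants),
            "plant_nodule_fresh_mass_mg":
                t.plant_nodule_fresh_mass_mg.sample(rng, n_plants),
            "plant_nodule_dry_mass_mg":
                t.plant_nodule_dry_mass_mg.sample(rng, n_plants),
            "plant_nodule_volume_mm3":
                t.plant_nodule_volume_mm3.sample(rng, n_plants),
            "ethylene_nmol": ara * 1.0e3,
            "ara_incubation_h": 1.0,
        }))
    return pd.concat(frames, ignore_index=True)


#: fraction of whole-plant fixation attributed to each tissue fraction
_FIXATION_SPLIT = {"shoot": 0.55, "root": 0.15, "nodule": 0.30}
#: total N (µg) per tissue fraction used when inverting APE
_TOTAL_N_UG = {"shoot": 12_000.0, "root": 6_000.0, "nodule": 3_000.0}


def generate_isotope_table(gt: GroundTruth, n_plants: int, seed: int,
                           gas_fraction: float = 0.20,
                           incubation_h: float = 2.0) -> pd.DataFrame:
    """Per-plant-fraction 15N atom% and total N rows.

    Atom percents are chosen so that summing the literal per-fraction
    rates and converting to µmol N2/h recovers each plant's sampled
    whole-plant fixation rate.
    """
    if n_plants < 2:
        raise ValueError("need at least two plants per host")
    rng = np.random.default_rng(_child_seed(seed, "isotope"))
    records = []
    factor = 1.0 / (4.0 * gas_fraction)
    for host in ("bean", "pea"):
        t = gt.host(host)
        rate = t.fixation_per_plant_umol_h.sample(rng, n_plants)
        for i in range(n_plants):
            for fraction, split in _FIXATION_SPLIT.items():
                ug_per_h = rate[i] * N2_MOLAR_MASS * split
                total_n = _TOTAL_N_UG[fraction]
                excess = ug_per_h * 100.0 / (total_n * factor)
                records.append({
                    "plant_id": f"{host}_{i + 1}",
                    "host": host,
                    "fraction": fraction,
                    "atom_percent_15N": N15_NATURAL_ABUNDANCE + excess,
                    "total_N_ug": total_n,
                    "incubation_h": incubation_h,
                    "gas_fraction_15N2": gas_fraction,
                })
    return pd.DataFrame.from_records(records)


def _bean_section_row(v_n: float, v_iz: float, f_c: float) -> dict:
    r = (3.0 * v_n / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_iz = (3.0 * v_iz / (4.0 * math.pi)) ** (1.0 / 3.0)
    a_iz = math.pi * r_iz**2
    return {"A_nod": math.pi * r**2, "F_dmax": 2.0 * r, "F_dmin": 2.0 * r,
            "A_iz": a_iz, "F_dmax_iz": 2.0 * r_iz, "F_dmin_iz": 2.0 * r_iz,
            "A_i": f_c * a_iz}


def _pea_section_row(v_n: float, v_iz: float, f_c: float,
                     cap_fraction: float, aspect: float) -> dict:
    # hemispherical cap: V_c = (2/3)π r³, chord c = 2r, sagitta h = r
    v_c = cap_fraction * v_n
    v_b = v_n - v_c
    r_cap = (3.0 * v_c / (2.0 * math.pi)) ** (1.0 / 3.0)
    # body cylinder with length = aspect × diameter
    d = (4.0 * v_b / (math.pi * aspect)) ** (1.0 / 3.0)
    l_c = aspect * d
    # infected zone: coaxial cylinder of the same length
    d_iz = math.sqrt(4.0 * v_iz / (math.pi * l_c))
    a_iz = d_iz * l_c
    return {"c": 2.0 * r_cap, "h": r_cap, "A_body": d * l_c, "l_c": l_c,
            "A_iz": a_iz, "l_iz": l_c, "A_i": f_c * a_iz}


def generate_sections(gt: GroundTruth, n_nodules: int,
                      seed: int) -> dict[str, pd.DataFrame]:
    """Section-measurement tables geometrically consistent with the models.

    For each sampled nodule the generator draws a nodule volume, infected
    fraction and colonization density, then writes the exact section
    measurements of a sphere (bean) or hemispherical-cap + cylinder (pea)
    of those volumes, so the geometry stage inverts them exactly at zero
    noise.
    """
    if n_nodules < 1:
        raise ValueError("need at least one nodule")
    rng = np.random.default_rng(_child_seed(seed, "sections"))
    out: dict[str, pd.DataFrame] = {}
    for host in ("bean", "pea"):
        t = gt.host(host)
        v_n = t.nodule_volume_mm3.sample(rng, n_nodules)
        infected = np.clip(t.infected_fraction.sample(rng, n_nodules), 0.0, 0.95)
        f_c = np.clip(t.colonization_density.sample(rng, n_nodules), 0.05, 1.0)
        # V_i = infected × V_n and V_i = f_c × V_iz  =>  V_iz = infected V_n / f_c
        v_iz = np.minimum(infected * v_n / f_c, 0.98 * v_n)
        rows = []
        for i in range(n_nodules):
            if host == "bean":
                row = _bean_section_row(v_n[i], v_iz[i], f_c[i])
            else:
                row = _pea_section_row(v_n[i], v_iz[i], f_c[i],
                                       t.cap_volume_fraction,
                                       t.body_aspect_ratio)
            row["nodule_id"] = f"{host}_nod_{i + 1}"
            rows.append(row)
        out[host] = pd.DataFrame(rows)
    return out


def generate_segmentation(gt: GroundTruth, n_bacteroids: int,
                          seed: int) -> pd.DataFrame:
    """Per-bacteroid segmentation volumes and surface areas.

    Surface areas scale as V^(2/3) around the host mean shape factor and
    are floored at the spherical (isoperimetric) minimum.
    """
    if n_bacteroids < 1:
        raise ValueError("need at least one bacteroid")
    rng = np.random.default_rng(_child_seed(seed, "segmentation"))
    frames = []
    for host in ("bean", "pea"):
        t = gt.host(host)
        vol = t.bacteroid_volume_um3.sample(rng, n_bacteroids)
        shape = t.bacteroid_surface_um2.mean / t.bacteroid_volume_um3.mean ** (2.0 / 3.0)
        noise = Param(1.0, t.bacteroid_surface_um2.cv / 3.0).sample(rng, n_bacteroids) \
            if t.bacteroid_surface_um2.cv > 0 else np.ones(n_bacteroids)
        surface = shape * vol ** (2.0 / 3.0) * noise
        floor = (36.0 * math.pi * vol**2) ** (1.0 / 3.0)
        surface = np.maximum(surface, floor * (1 + 1e-9))
        frames.append(pd.DataFrame({
            "bacteroid_id": [f"{host}_b{i + 1}" for i in range(n_bacteroids)],
            "host": host,
            "volume_um3": vol,
            "surface_um2": surface,
            "dataset_id": f"{host}_sbfsem_1",
        }))
    return pd.concat(frames, ignore_index=True)


def generate_packing(gt: GroundTruth, n_samples: int, seed: int,
                     dims_um: tuple[float, float, float] = (8.0, 8.0, 2.0)
                     ) -> pd.DataFrame:
    """Packing subvolumes (default 8 × 8 × 2 µm) with occupied volumes."""
    if n_samples < 1:
        raise ValueError("need at least one packing sample")
    rng = np.random.default_rng(_child_seed(seed, "packing"))
    x, y, z = dims_um
    total = x * y * z
    frames = []
    for host in ("bean", "pea"):
        t = gt.host(host)
        frac = np.clip(t.packing_fraction.sample(rng, n_samples), 0.0, 1.0)
        frames.append(pd.DataFrame({
            "sample_id": [f"{host}_pack_{i + 1}" for i in range(n_samples)],
            "host": host,
            "X_um": x, "Y_um": y, "Z_um": z,
            "occupied_um3": frac * total,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_flow_events(seed: int, labeled_per_ml: float = 1.0e6,
                         volume_ul: float = 50.0,
                         dim_fraction: float = 0.20) -> pd.DataFrame:
    """Flow-cytometry event table with a planted labeled concentration.

    Labeled bacteroids carry bright fluorescence (well above the 3,000 FI
    yellow gate) and singlet-like aspect ratios; a ``dim_fraction`` of
    additional contaminant events sits below the gate.  The labeled event
    count is Poisson around concentration × analyzed volume.
    """
    if labeled_per_ml <= 0 or volume_ul <= 0:
        raise ValueError("concentration and volume must be positive")
    rng = np.random.default_rng(_child_seed(seed, "flow"))
    n_labeled = rng.poisson(labeled_per_ml * volume_ul / 1.0e3)
    n_dim = rng.poisson(dim_fraction * labeled_per_ml * volume_ul / 1.0e3)
    labeled = pd.DataFrame({
        "FSC": rng.lognormal(math.log(5.0e4), 0.4, n_labeled),
        "SSC": rng.lognormal(math.log(2.0e4), 0.4, n_labeled),
        "SSC_aspect_ratio": rng.uniform(0.6, 1.0, n_labeled),
        "YFP_FI": rng.lognormal(math.log(3.0e4), 0.5, n_labeled),
        "labeled": True,
    })
    labeled["YFP_FI"] = np.maximum(labeled["YFP_FI"], 3_500.0)
    dim = pd.DataFrame({
        "FSC": rng.lognormal(math.log(2.0e4), 0.6, n_dim),
        "SSC": rng.lognormal(math.log(1.0e4), 0.6, n_dim),
        "SSC_aspect_ratio": rng.uniform(0.1, 1.0, n_dim),
        "YFP_FI": rng.uniform(0.0, 2_500.0, n_dim),
        "labeled": False,
    })
    events = pd.concat([labeled, dim], ignore_index=True)
    events.attrs["volume_analyzed_ul"] = volume_ul
    events.attrs["labeled_per_ml"] = labeled_per_ml
    return events.sample(frac=1.0, random_state=int(seed) % 2**31
                         ).reset_index(drop=True)


# peptide-table constants
_HI3 = "PHS2_RABIT"
_RESPONSE_PER_FMOL = 1.0e6  # arbitrary instrument response, intensity/fmol
_B_D = {"bean": 1_202_531.0, "pea": 608_974.0}


def generate_peptide_table(gt: GroundTruth, n_reps: int = 3, seed: int = 0,
                           intensity_cv: float = 0.10,
                           response_cv: float = 0.0,
                           n_peptides: int = 5,
                           include_decoys: bool = True) -> pd.DataFrame:
    """MaxQuant-dialect modification-specific peptide table.

    Peptide intensity = instrument response × loaded fmol × per-peptide
    response factor × lognormal noise.  The loaded fmol of each protein
    follows its true per-bacteroid copies (per-replicate lognormal around
    the panel truth at ``intensity_cv``) via the per-load bacteroid counts;
    the Hi3 standard is present at a fixed 12.5 fmol in every sample.
    Decoy rows (missed cleavages, disallowed modifications) and split
    Met-oxidation rows exercise the top3 filter.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if n_peptides < 3:
        raise ValueError("every protein needs >= 3 peptides")
    rng = np.random.default_rng(_child_seed(seed, "peptides"))
    samples = [f"{host}_{r + 1}" for host in ("bean", "pea")
               for r in range(n_reps)]
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def pep_seq() -> str:
        return "".join(rng.choice(aa, rng.integers(8, 15))) + "K"

    rows: list[dict] = []
    proteins = dict(gt.protein_copies)
    for protein, copies in proteins.items():
        seqs = [pep_seq() for _ in range(n_peptides)]
        rf = (np.ones(n_peptides) if response_cv == 0.0
              else Param(1.0, response_cv).sample(rng, n_peptides))
        # per-sample loaded fmol from true copies per bacteroid
        fmol = {}
        for sample in samples:
            host = sample.split("_")[0]
            true_copies = copies[0] if host == "bean" else copies[1]
            rep_copies = Param(true_copies, intensity_cv).sample(rng, 1)[0] \
                if intensity_cv > 0 else true_copies
            fmol[sample] = rep_copies * _B_D[host] / COPIES_PER_FMOL
        for j, seq in enumerate(seqs):
            base = {s: _RESPONSE_PER_FMOL * fmol[s] * rf[j] for s in samples}
            if j == 0:
                # split between unmodified and Met-oxidized rows; top3 sums
                for mods, share in (("Unmodified", 0.7), ("Oxidation (M)", 0.3)):
                    rows.append({"Sequence": seq, "Modifications": mods,
                                 "Missed cleavages": 0, "Proteins": protein,
                                 "Unique": "yes",
                                 **{f"Intensity {s}": share * base[s]
                                    for s in samples}})
            else:
                rows.append({"Sequence": seq, "Modifications": "Unmodified",
                             "Missed cleavages": 0, "Proteins": protein,
                             "Unique": "yes",
                             **{f"Intensity {s}": base[s] for s in samples}})
        if include_decoys:
            rows.append({"Sequence": pep_seq(), "Modifications": "Unmodified",
                         "Missed cleavages": 1, "Proteins": protein,
                         "Unique": "yes",
                         **{f"Intensity {s}": 10.0 * base[s] for s in samples}})
            rows.append({"Sequence": pep_seq(),
                         "Modifications": "Phospho (STY)",
                         "Missed cleavages": 0, "Proteins": protein,
                         "Unique": "yes",
                         **{f"Intensity {s}": 5.0 * base[s] for s in samples}})
    # Hi3 spike: fixed 12.5 fmol in every sample
    for j in range(n_peptides):
        noise = (np.ones(len(samples)) if intensity_cv == 0.0
                 else Param(1.0, intensity_cv).sample(rng, len(samples)))
        rows.append({"Sequence": pep_seq(), "Modifications": "Unmodified",
                     "Missed cleavages": 0, "Proteins": _HI3, "Unique": "yes",
                     **{f"Intensity {s}": _RESPONSE_PER_FMOL * 12.5 * noise[i]
                        for i, s in enumerate(samples)}})
    return pd.DataFrame.from_records(rows)


def generate_mass_fractions(n_proteins: int, n_half: int,
                            seed: int = 0, jitter_cv: float = 0.0
                            ) -> np.ndarray:
    """Proteome mass fractions (%) whose top ``n_half`` sum to 50%.

    A geometric abundance series f_i ∝ ρ^i with ρ solved so the top
    ``n_half`` of ``n_proteins`` carry exactly half the mass; optional
    lognormal jitter preserves the skew approximately.
    """
    from scipy.optimize import brentq
    if not 0 < n_half < n_proteins:
        raise ValueError("need 0 < n_half < n_proteins")

    def gap(rho: float) -> float:
        i = np.arange(n_proteins)
        w = rho**i
        return w[:n_half].sum() / w.sum() - 0.5

    rho = brentq(gap, 1e-6, 1.0 - 1e-9)
    w = rho ** np.arange(n_proteins)
    if jitter_cv > 0:
        rng = np.random.default_rng(_child_seed(seed, "rna"))
        w = w * Param(1.0, jitter_cv).sample(rng, n_proteins)
    return 100.0 * np.sort(w / w.sum())[::-1]


def generate_rna_protein_pairs(n_genes: int, r: float, seed: int = 0
                               ) -> pd.DataFrame:
    """Paired normalized RNA counts and protein masses with planted
    log-scale Pearson correlation ``r``."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie in (-1, 1)")
    if n_genes < 3:
        raise ValueError("need at least three genes")
    rng = np.random.default_rng(_child_seed(seed, "rna"))
    cov = [[1.0, r], [r, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, n_genes)
    return pd.DataFrame({
        "gene": [f"gene_{i + 1}" for i in range(n_genes)],
        "rna_norm_counts": 10.0 ** (3.0 + 0.8 * z[:, 0]),
        "protein_fg_per_bacteroid": 10.0 ** (0.0 + 0.8 * z[:, 1]),
    })


@dataclass(frozen=True)
class SyntheticBundle:
    """Every raw table the pipeline consumes, plus provenance."""

    plant_table: pd.DataFrame
    isotope_table: pd.DataFrame
    bean_section_table: pd.DataFrame
    pea_section_table: pd.DataFrame
    segmentation_table: pd.DataFrame
    packing_table: pd.DataFrame
    flow_event_table: pd.DataFrame
    peptide_table: pd.DataFrame
    rna_count_table: pd.DataFrame
    ground_truth: GroundTruth
    seed: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in (
            "plant_table", "isotope_table", "bean_section_table",
            "pea_section_table", "segmentation_table", "packing_table",
            "flow_event_table", "peptide_table", "rna_count_table")}

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def generate_bundle(gt: GroundTruth | None = None, seed: int = 0,
                    n_plants: int = 11, n_nodules: int = 8,
                    n_bacteroids: int = 240, n_packing: int = 8,
                    n_reps: int = 3) -> SyntheticBundle:
    """Generate the full mutually consistent input bundle.

    Default cohort sizes mirror the study: 11 plants, 8 sectioned nodules,
    ~240 segmented bacteroids, 3 proteomics replicates per host.
    """
    gt = gt or GroundTruth.default(seed)
    sections = generate_sections(gt, n_nodules, seed)
    return SyntheticBundle(
        plant_table=generate_plants(gt, n_plants, seed),
        isotope_table=generate_isotope_table(gt, n_plants, seed),
        bean_section_table=sections["bean"],
        pea_section_table=sections["pea"],
        segmentation_table=generate_segmentation(gt, n_bacteroids, seed),
        packing_table=generate_packing(gt, n_packing, seed),
        flow_event_table=generate_flow_events(seed),
        peptide_table=generate_peptide_table(gt, n_reps=n_reps, seed=seed),
        rna_count_table=generate_rna_protein_pairs(197, 0.84, seed),
        ground_truth=gt,
        seed=seed,
    )
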