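"""Cohort comparison tables and whole-pipeline orchestration.

``compare_groups`` produces one summary-table row: group means ± SE, a
Student's unpaired t-test, and a bean/pea fold change in one of two
conventions (ratio of group means, or mean of per-replicate ratios).

``derive_table1`` assembles the derived rows of the host-comparison table
from raw per-host summary values — nodule density from dry mass and
volume, total bacteroid volume from infected volume and packing fraction,
bacteroid counts, protein densities, and occupied-volume percentages —
each carrying provenance naming its parent rows.

``run_pipeline`` chains simulation (or table loading), geometry, census,
rates and proteomics, writing TSV outputs plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import census, geometry, quant, rates
from .simulate import GroundTruth, generate_bundle
from .units import MM3_PER_CM3

__all__ = ["ComparisonRow", "compare_groups", "derive_table1", "run_pipeline"]

log = logging.getLogger("nodusym")


@dataclass(frozen=True)
class ComparisonRow:
    """One host-comparison row: means ± SE, fold change (bean/pea), p."""

    parameter: str
    bean_mean: float
    bean_se: float
    pea_mean: float
    pea_se: float
    n_bean: int
    n_pea: int
    fold_change: float
    p_value: float


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0


def compare_groups(bean_values, pea_values, parameter: str = "",
                   mode: str = "ratio_of_means",
                   test: str = "student") -> ComparisonRow:
    """Compare two host cohorts of per-replicate values.

    ``mode='ratio_of_means'`` (the summary-table convention) takes
    mean(bean)/mean(pea); ``'mean_of_ratios'`` pairs replicates and
    averages bean_i/pea_i (requires equal lengths).  ``test`` selects the
    Student (equal-variance, default) or Welch t-test.
    """
    bean = np.asarray(bean_values, dtype=float)
    pea = np.asarray(pea_values, dtype=float)
    if bean.size < 2 or pea.size < 2:
        raise ValueError("need at least two values per group")
    if mode == "ratio_of_means":
        if pea.mean() == 0:
            raise ValueError("pea mean is zero; fold change undefined")
        fold = bean.mean() / pea.mean()
    elif mode == "mean_of_ratios":
        if bean.size != pea.size:
            raise ValueError("mean_of_ratios needs paired, equal-length groups")
        fold = float(np.mean(bean / pea))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if bean.std(ddof=1) == 0 and pea.std(ddof=1) == 0:
        p = 1.0 if np.isclose(bean.mean(), pea.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(bean, pea, equal_var=(test == "student")).pvalue)
    return ComparisonRow(parameter, float(bean.mean()), _se(bean),
                         float(pea.mean()), _se(pea), int(bean.size),
                         int(pea.size), float(fold), p)


# raw per-host keys accepted by derive_table1
RAW_KEYS = [
    "shoot_dry_mass_mg", "plant_nodule_dry_mass_mg", "plant_nodule_volume_mm3",
    "calculated_nodule_volume_mm3", "infected_volume_mm3", "packing_fraction",
    "bacteroid_volume_um3", "bacteroid_surface_um2", "sa_v_ratio",
    "protein_per_bacteroid_pg", "ara_per_plant_umol_h",
    "fixation_per_plant_umol_h",
]


def derive_table1(raw: dict) -> pd.DataFrame:
    """Derived host-comparison rows from raw per-host summary values.

    ``raw`` maps host ('bean'/'pea') to a dict of the RAW_KEYS present;
    every derivable row is emitted with provenance, and rows whose parents
    are missing are skipped (partial assembly is allowed).
    """
    hosts = ("bean", "pea")
    rows: list[dict] = []

    def have(*keys: str) -> bool:
        return all(k in raw.get(h, {}) for h in hosts for k in keys)

    def emit(parameter: str, fn, provenance: str) -> None:
        values = {h: fn(raw[h]) for h in hosts}
        rows.append({"parameter": parameter, "bean": values["bean"],
                     "pea": values["pea"],
                     "fold_change": values["bean"] / values["pea"],
                     "provenance": provenance})

    for key in RAW_KEYS:
        if have(key):
            emit(key, lambda r, k=key: r[k], "raw")
    if have("plant_nodule_dry_mass_mg", "plant_nodule_volume_mm3"):
        emit("nodule_density_mg_cm3",
             lambda r: r["plant_nodule_dry_mass_mg"]
             / (r["plant_nodule_volume_mm3"] / MM3_PER_CM3),
             "derived-from: plant_nodule_dry_mass_mg, plant_nodule_volume_mm3")
    if have("infected_volume_mm3", "packing_fraction"):
        emit("total_bacteroid_volume_mm3",
             lambda r: census.total_bacteroid_volume(
                 r["infected_volume_mm3"], r["packing_fraction"]),
             "derived-from: infected_volume_mm3, packing_fraction")
        if have("bacteroid_volume_um3"):
            emit("bacteroids_per_nodule",
                 lambda r: census.bacteroids_per_nodule(
                     census.total_bacteroid_volume(r["infected_volume_mm3"],
                                                   r["packing_fraction"]),
                     r["bacteroid_volume_um3"]),
                 "derived-from: infected_volume_mm3, packing_fraction, "
                 "bacteroid_volume_um3")
        if have("calculated_nodule_volume_mm3"):
            emit("pct_nodule_volume_bacteroids",
                 lambda r: 100.0 * census.total_bacteroid_volume(
                     r["infected_volume_mm3"], r["packing_fraction"])
                 / r["calculated_nodule_volume_mm3"],
                 "derived-from: infected_volume_mm3, packing_fraction, "
                 "calculated_nodule_volume_mm3")
    if have("protein_per_bacteroid_pg", "bacteroid_volume_um3"):
        emit("protein_density_pg_um3",
             lambda r: census.protein_density(r["protein_per_bacteroid_pg"],
                                              r["bacteroid_volume_um3"]),
             "derived-from: protein_per_bacteroid_pg, bacteroid_volume_um3")
    return pd.DataFrame(rows)


def _geometry_summary(bundle) -> dict:
    bean = geometry.bean_volumes_table(bundle.bean_section_table)
    pea = geometry.pea_volumes_table(bundle.pea_section_table)
    out = {}
    for host, table in (("bean", bean), ("pea", pea)):
        out[host] = {
            "calculated_nodule_volume_mm3": float(table["V_n"].mean()),
            "infected_volume_mm3": float(table["V_i"].mean()),
            "mean_f_c": float(table["f_c"].mean()),
            "volumes_table": table,
        }
    return out

def _census_summaries(bundle, geo: dict) -> dict:
    out = {}
    for host in ("bean", "pea"):
        seg = bundle.segmentation_table.query("host == @host")
        pack = bundle.packing_table.query("host == @host")
        protein = bundle.ground_truth.host(host).protein_per_bacteroid_pg.mean
        out[host] = census.census_summary(
            seg, pack, geo[host]["infected_volume_mm3"], protein)
    return out


def _rate_tables(bundle, geo: dict, cen: dict) -> dict:
    plants = bundle.plant_table
    iso = bundle.isotope_table
    out = {}
    for host in ("bean", "pea"):
        hp = plants.query("host == @host")
        ara = np.array([rates.ara_rate(e, h) for e, h in
                        zip(hp["ethylene_nmol"], hp["ara_incubation_h"])])
        fix = []
        for plant_id, rows in iso.query("host == @host").groupby("plant_id"):
            ms = [rates.IsotopeMeasurement(
                fraction=r["fraction"], atom_percent_15n=r["atom_percent_15N"],
                total_n_ug=r["total_N_ug"], incubation_h=r["incubation_h"],
                gas_fraction_15n2=r["gas_fraction_15N2"])
                for _, r in rows.iterrows()]
            fix.append(rates.plant_fixation_rate(ms))
        nodules_per_plant = float(hp["nodule_count"].mean())
        denom = rates.RateDenominators(
            sdw_g=float(hp["shoot_dry_mass_mg"].mean()) / 1.0e3,
            nodule_volume_cm3=float(hp["plant_nodule_volume_mm3"].mean())
            / MM3_PER_CM3,
            nodule_dry_mass_mg=float(hp["plant_nodule_dry_mass_mg"].mean()),
            infected_volume_mm3=geo[host]["infected_volume_mm3"]
            * nodules_per_plant,
            bacteroid_count=cen[host]["bacteroids_per_nodule"]
            * nodules_per_plant,
            bacteroid_protein_pg=cen[host]["protein_per_bacteroid_pg"],
            bacteroid_volume_um3=cen[host]["mean_volume_um3"],
        )
        out[host] = {
            "ara": asdict(rates.normalize_rate(float(np.mean(ara)), denom)),
            "n2_fixation": asdict(rates.normalize_rate(float(np.mean(fix)),
                                                       denom)),
        }
    return out


def run_pipeline(config: dict | str | Path, out_dir, simulate: bool = False,
                 seed: int | None = None) -> dict:
    """Run the full analysis and write outputs under ``out_dir``.

    ``config`` is a dict (or path to a YAML file) with optional keys
    ``seed``, ``n_plants``, ``n_nodules``, ``n_bacteroids``, ``n_packing``,
    ``n_reps`` when simulating, or an ``inputs`` section naming table
    paths.  Returns the JSON-serializable summary that is also written to
    ``summary.json``.
    """
    if not isinstance(config, dict):
        import yaml
        config = yaml.safe_load(Path(config).read_text()) or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))

    if simulate or config.get("simulate", False):
        bundle = generate_bundle(
            GroundTruth.default(seed), seed=seed,
            n_plants=int(config.get("n_plants", 11)),
            n_nodules=int(config.get("n_nodules", 8)),
            n_bacteroids=int(config.get("n_bacteroids", 240)),
            n_packing=int(config.get("n_packing", 8)),
            n_reps=int(config.get("n_reps", 3)))
    else:
        bundle = _load_bundle(config, seed)
    bundle.write(out / "inputs")

    log.info("geometry stage")
    geo = _geometry_summary(bundle)
    for host in ("bean", "pea"):
        geometry.write_volumes(geo[host]["volumes_table"],
                               out / f"geometry_{host}.tsv")
    log.info("census stage")
    cen = _census_summaries(bundle, geo)
    pd.DataFrame(cen).T.to_csv(out / "census.tsv", sep="\t")
    log.info("rates stage")
    rate = _rate_tables(bundle, geo, cen)
    pd.concat({h: pd.DataFrame(rate[h]).T for h in rate}).to_csv(
        out / "rates.tsv", sep="\t")

    summary: dict = {"seed": seed, "hosts": {}}
    quant_summary = None
    if bundle.peptide_table is not None and len(bundle.peptide_table):
        log.info("quant stage")
        q = quant.quantify(bundle.peptide_table)
        fc = quant.fold_change_table(q)
        q.to_csv(out / "quant.tsv", sep="\t", index=False)
        fc.to_csv(out / "table2_fold_changes.tsv", sep="\t")
        quant_summary = {
            "n_proteins": int(q["protein"].nunique()),
            "fold_changes_per_bacteroid":
                fc["fc_per_bacteroid"].round(6).to_dict(),
        }
    else:
        log.warning("no peptide table; quant stage skipped")

    raw = {}
    for host in ("bean", "pea"):
        hp = bundle.plant_table.query("host == @host")
        raw[host] = {
            "shoot_dry_mass_mg": float(hp["shoot_dry_mass_mg"].mean()),
            "plant_nodule_dry_mass_mg":
                float(hp["plant_nodule_dry_mass_mg"].mean()),
            "plant_nodule_volume_mm3":
                float(hp["plant_nodule_volume_mm3"].mean()),
            "calculated_nodule_volume_mm3":
                geo[host]["calculated_nodule_volume_mm3"],
            "infected_volume_mm3": geo[host]["infected_volume_mm3"],
            "packing_fraction": cen[host]["packing_fraction"],
            "bacteroid_volume_um3": cen[host]["mean_volume_um3"],
            "bacteroid_surface_um2": cen[host]["mean_surface_um2"],
            "sa_v_ratio": cen[host]["mean_sa_v"],
            "protein_per_bacteroid_pg": cen[host]["protein_per_bacteroid_pg"],
            "ara_per_plant_umol_h": rate[host]["ara"]["per_plant"],
            "fixation_per_plant_umol_h": rate[host]["n2_fixation"]["per_plant"],
        }
    table1 = derive_table1(raw)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    for host in ("bean", "pea"):
        summary["hosts"][host] = {
            **{k: v for k, v in raw[host].items()},
            "rates": rate[host],
            "census": {k: v for k, v in cen[host].items()},
        }
    summary["table1"] = table1.drop(columns="provenance").round(9).to_dict(
        orient="records")
    if quant_summary is not None:
        summary["quant"] = quant_summary
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary


def _load_bundle(config: dict, seed: int):
    """Assemble a bundle from user-supplied TSV paths (simulation-free)."""
    from .simulate import SyntheticBundle
    inputs = config.get("inputs")
    if inputs is None:
        raise ValueError("config needs an 'inputs' section or simulate=True")

    def read(key: str) -> pd.DataFrame:
        if key not in inputs:
            raise ValueError(f"config inputs missing {key!r}")
        return pd.read_csv(inputs[key], sep="\t")

    peptides = (pd.read_csv(inputs["peptide_table"], sep="\t")
                if "peptide_table" in inputs else pd.DataFrame())
    rna = (pd.read_csv(inputs["rna_count_table"], sep="\t")
           if "rna_count_table" in inputs else pd.DataFrame())
    flow = (pd.read_csv(inputs["flow_event_table"], sep="\t")
            if "flow_event_table" in inputs else pd.DataFrame())
    return SyntheticBundle(
        plant_table=read("plant_table"),
        isotope_table=read("isotope_table"),
        bean_section_table=read("bean_section_table"),
        pea_section_table=read("pea_section_table"),
        segmentation_table=read("segmentation_table"),
        packing_table=read("packing_table"),
        flow_event_table=flow,
        peptide_table=peptides,
        rna_count_table=rna,
        ground_truth=GroundTruth.default(seed),
        seed=seed,
    )
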