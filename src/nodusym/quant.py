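"""Absolute label-free proteome quantification (top3 + Hi3 spike).

A protein's abundance signal is the mean intensity of its three most
intense unique peptides (top3), computed per sample from a MaxQuant-style
modification-specific peptide table.  Only unmodified peptides and peptides
with oxidized methionine qualify, no missed cleavages are allowed, and a
sequence observed both unmodified and oxidized contributes the sum of the
two intensities.  Dividing by the top3 signal of a spiked Hi3 standard of
known amount (12.5 fmol of rabbit glycogen phosphorylase, PHS2_RABIT)
converts intensity to femtomoles loaded, and the Avogadro-derived constant
6.0221413e8 copies/fmol converts to protein copies.

Copies are then expressed at five scales with host-specific constants:
per bacteroid (dividing by B_D, the number of bacteroids the 380 ng load
derives from), per µm³ bacteroid volume, per nodule, per mm³ nodule volume,
and per pg bacteroid protein.  Fold changes between hosts use ratios of
group means with Welch's two-sample t-test on per-replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .units import COPIES_PER_FMOL

__all__ = [
    "QuantConstants",
    "top3",
    "top3_all",
    "absolute_abundance",
    "copy_numbers",
    "quantify",
    "median_ratio_normalize",
    "fold_change_table",
    "proteome_mass_rank",
    "distribution_compare",
    "rna_protein_correlation",
    "SCALES",
]

#: copy-number scale column names, in cascade order
SCALES = ["per_bacteroid", "per_bacteroid_volume", "per_nodule",
          "per_nodule_volume", "per_unit_protein"]

#: peptide modifications that qualify for top3
ALLOWED_MODS = {"Unmodified", "Oxidation (M)"}

#: default Hi3 standard accession (rabbit glycogen phosphorylase)
HI3_ACCESSION = "PHS2_RABIT"


@dataclass(frozen=True)
class QuantConstants:
    """Host-specific constants of the copy-number cascade.

    b_d: bacteroids the 380 ng protein load derives from; b_vol: mean
    bacteroid volume (µm³); b_nod: bacteroids per nodule; nod_vol: mean
    nodule volume (mm³); b_p: protein per bacteroid (pg).
    """

    hi3_spike_fmol: float = 12.5
    copies_per_fmol: float = COPIES_PER_FMOL
    loaded_protein_ng: float = 380.0
    b_d: dict = field(default_factory=lambda: {"bean": 1_202_531.0,
                                               "pea": 608_974.0})
    b_vol: dict = field(default_factory=lambda: {"bean": 0.93, "pea": 4.50})
    b_nod: dict = field(default_factory=lambda: {"bean": 5.28e8, "pea": 1.63e8})
    nod_vol: dict = field(default_factory=lambda: {"bean": 6.07, "pea": 4.61})
    b_p: dict = field(default_factory=lambda: {"bean": 0.32, "pea": 0.62})


def _qualifying(rows: pd.DataFrame, sample: str) -> pd.Series:
    """Per-sequence qualifying intensities: filter, then sum mod states."""
    ok = rows[(rows["Missed cleavages"] == 0)
              & rows["Modifications"].isin(ALLOWED_MODS)
              & (rows["Unique"].astype(str).str.lower().isin(["yes", "true", "1"]))]
    col = f"Intensity {sample}"
    if col not in rows.columns:
        raise ValueError(f"peptide table has no column {col!r}")
    return ok.groupby("Sequence")[col].sum()


def top3(rows: pd.DataFrame, protein: str, sample: str,
         strict: bool = True) -> float:
    """top3 intensity of one protein in one sample.

    Unique, fully cleaved peptides that are unmodified or Met-oxidized are
    grouped by sequence (summing the two modification states) and the three
    highest intensities are averaged.  With fewer than three qualifying
    peptides, ``strict`` raises; otherwise the available ones are averaged.
    """
    mine = rows[rows["Proteins"] == protein]
    intensities = _qualifying(mine, sample)
    intensities = intensities[intensities > 0].sort_values(ascending=False)
    if len(intensities) < 3 and strict:
        raise ValueError(
            f"protein {protein!r} has {len(intensities)} qualifying peptides "
            f"in sample {sample!r}; 3 required in strict mode")
    if len(intensities) == 0:
        return 0.0
    return float(intensities.head(3).mean())


def top3_all(peptides: pd.DataFrame, samples: list[str],
             strict: bool = True) -> pd.DataFrame:
    """top3 intensities for every protein × sample; proteins with fewer
    than three qualifying peptides are dropped in strict mode (with a
    ``flagged`` marker column otherwise)."""
    out: dict[str, dict[str, float]] = {}
    flagged: dict[str, bool] = {}
    for protein, rows in peptides.groupby("Proteins"):
        values = {}
        short = False
        for sample in samples:
            try:
                values[sample] = top3(rows, protein, sample, strict=True)
            except ValueError:
                if strict:
                    values = {}
                    break
                values[sample] = top3(rows, protein, sample, strict=False)
                short = True
        if values:
            out[protein] = values
            flagged[protein] = short
    table = pd.DataFrame.from_dict(out, orient="index")[samples]
    table.index.name = "protein"
    if not strict:
        table["flagged"] = pd.Series(flagged)
    return table


def absolute_abundance(top3_protein: float, top3_hi3: float,
                       spike_fmol: float = 12.5) -> float:
    """Protein amount loaded (fmol): (top3 / top3_Hi3) × spike."""
    if top3_hi3 <= 0:
        raise ValueError("Hi3 standard signal must be positive")
    if top3_protein < 0:
        raise ValueError("top3 intensity must be non-negative")
    return (top3_protein / top3_hi3) * spike_fmol


def copy_numbers(a_b_fmol: float, k: QuantConstants, host: str) -> dict:
    """Copy-number cascade for one protein in one sample.

    C_p = A_b × copies/fmol; then per bacteroid (÷ B_D), per bacteroid
    volume (÷ B_vol), per nodule (× B_nod), per nodule volume (÷ Nod_vol),
    per unit protein (÷ B_P).
    """
    if host not in k.b_d:
        raise ValueError(f"unknown host {host!r}")
    if a_b_fmol < 0:
        raise ValueError("abundance must be non-negative")
    c_p = a_b_fmol * k.copies_per_fmol
    per_bacteroid = c_p / k.b_d[host]
    per_nodule = per_bacteroid * k.b_nod[host]
    return {
        "A_b_fmol": a_b_fmol,
        "C_p": c_p,
        "per_bacteroid": per_bacteroid,
        "per_bacteroid_volume": per_bacteroid / k.b_vol[host],
        "per_nodule": per_nodule,
        "per_nodule_volume": per_nodule / k.nod_vol[host],
        "per_unit_protein": per_bacteroid / k.b_p[host],
    }


def median_ratio_normalize(top3_table: pd.DataFrame,
                           samples: list[str]) -> pd.DataFrame:
    """Median-ratio normalization of replicate top3 intensities.

    Each sample column is divided by the median, over proteins, of its
    ratio to the geometric-mean reference column.  Off by default in
    :func:`quantify`; a documented stand-in for regression-based replicate
    normalization.
    """
    values = top3_table[samples].replace(0, np.nan)
    log_ref = np.log(values).mean(axis=1)
    out = top3_table.copy()
    for sample in samples:
        ratios = np.log(values[sample]) - log_ref
        out[sample] = top3_table[sample] / np.exp(np.nanmedian(ratios))
    return out


def _host_of(sample: str) -> str:
    return sample.split("_")[0]


def quantify(peptides: pd.DataFrame, k: QuantConstants | None = None,
             hi3_accession: str = HI3_ACCESSION, strict: bool = True,
             normalize: bool = False) -> pd.DataFrame:
    """Full absolute quantification of a merged peptide table.

    Sample columns are auto-detected from ``Intensity <host>_<rep>``
    headers.  Returns a long table: one row per protein × sample with the
    fmol abundance and all five copy-number scales.
    """
    k = k or QuantConstants()
    samples = [c.removeprefix("Intensity ") for c in peptides.columns
               if c.startswith("Intensity ")]
    if not samples:
        raise ValueError("no 'Intensity <sample>' columns found")
    table = top3_all(peptides, samples, strict=strict)
    if normalize:
        table = median_ratio_normalize(table, samples)
    if hi3_accession not in table.index:
        raise ValueError(f"Hi3 standard {hi3_accession!r} not quantified")
    records = []
    for protein, row in table.iterrows():
        if protein == hi3_accession:
            continue
        for sample in samples:
            host = _host_of(sample)
            if host not in k.b_d:
                continue
            a_b = absolute_abundance(row[sample], table.loc[hi3_accession, sample],
                                     k.hi3_spike_fmol)
            rec = {"protein": protein, "sample": sample, "host": host}
            rec.update(copy_numbers(a_b, k, host))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch p-value, with the degenerate zero-variance cases defined."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    tol_a = 1e-9 * max(abs(a.mean()), 1.0)
    tol_b = 1e-9 * max(abs(b.mean()), 1.0)
    if a.std(ddof=1) <= tol_a and b.std(ddof=1) <= tol_b:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fold_change_table(quant: pd.DataFrame, numerator: str = "pea",
                      denominator: str = "bean", alpha: float = 0.05,
                      log_test: bool = False) -> pd.DataFrame:
    """Per-protein fold changes (numerator/denominator) at all five scales.

    Fold change is the ratio of group means per scale; Welch's two-sample
    t-test runs on per-replicate per-bacteroid copies (optionally
    log-transformed) for proteins seen in both hosts.
    """
    out = []
    for protein, rows in quant.groupby("protein"):
        num = rows[rows["host"] == numerator]
        den = rows[rows["host"] == denominator]
        if len(num) < 2 or len(den) < 2:
            continue
        rec: dict = {"protein": protein}
        for scale in SCALES:
            den_mean = den[scale].mean()
            if den_mean == 0:
                raise ValueError(f"zero {denominator} mean for {protein!r}")
            rec[f"fc_{scale}"] = num[scale].mean() / den_mean
        a = num["per_bacteroid"].to_numpy()
        b = den["per_bacteroid"].to_numpy()
        if log_test:
            a, b = np.log(a), np.log(b)
        rec["p_value"] = _welch(a, b)
        rec["significant"] = rec["p_value"] < alpha
        out.append(rec)
    return pd.DataFrame.from_records(out).set_index("protein")


def proteome_mass_rank(mass_fractions, threshold: float = 50.0
                       ) -> tuple[pd.DataFrame, int]:
    """Rank proteins by proteome mass fraction and find n to the threshold.

    Returns the descending-sorted cumulative table and the smallest number
    of proteins whose cumulative mass fraction reaches ``threshold`` %.
    """
    fractions = np.sort(np.asarray(mass_fractions, dtype=float))[::-1]
    if fractions.size == 0:
        raise ValueError("empty mass-fraction input")
    cumulative = np.cumsum(fractions)
    ranked = pd.DataFrame({"rank": np.arange(1, fractions.size + 1),
                           "mass_fraction": fractions,
                           "cumulative": cumulative})
    reached = np.nonzero(cumulative >= threshold - 1e-9)[0]
    if reached.size == 0:
        raise ValueError("mass fractions never reach the threshold")
    return ranked, int(reached[0] + 1)


def distribution_compare(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test on mass fractions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rna_protein_correlation(protein_mass, rna_counts,
                            log: bool = False) -> tuple[float, float]:
    """Pearson r and r² between protein mass and normalized RNA counts."""
    x = np.asarray(rna_counts, dtype=float)
    y = np.asarray(protein_mass, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if log:
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
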