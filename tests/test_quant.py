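"""top3/Hi3 quantification, copy-number cascade and proteome statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nodusym import quant
from nodusym.quant import (QuantConstants, absolute_abundance, copy_numbers,
                           distribution_compare, fold_change_table,
                           proteome_mass_rank, rna_protein_correlation, top3)
from nodusym.simulate import generate_mass_fractions, generate_peptide_table
from nodusym.units import COPIES_PER_FMOL


def peptide_rows(intensities, protein="P1", sample="bean_1", **overrides):
    rows = []
    for i, val in enumerate(intensities):
        row = {"Sequence": f"PEPTIDE{i}K", "Modifications": "Unmodified",
               "Missed cleavages": 0, "Proteins": protein, "Unique": "yes",
               f"Intensity {sample}": float(val)}
        row.update(overrides)
        rows.append(row)
    return pd.DataFrame(rows)


class TestTop3:
    def test_average_of_three_highest(self):
        df = peptide_rows([10, 8, 6, 4])
        assert top3(df, "P1", "bean_1") == pytest.approx(8.0)

    def test_oxidized_and_unmodified_forms_are_summed(self):
        df = peptide_rows([7, 6])
        ox = peptide_rows([5], protein="P1")
        ox.loc[0, "Sequence"] = "SHAREDK"
        extra = peptide_rows([3], protein="P1", Modifications="Oxidation (M)")
        extra.loc[0, "Sequence"] = "SHAREDK"
        df = pd.concat([df, ox, extra], ignore_index=True)
        # SHAREDK contributes 5 + 3 = 8; top3 = (8 + 7 + 6) / 3
        assert top3(df, "P1", "bean_1") == pytest.approx(7.0)

    def test_missed_cleavages_excluded(self):
        df = peptide_rows([10, 8, 6])
        decoy = peptide_rows([100], **{"Missed cleavages": 1})
        decoy.loc[0, "Sequence"] = "DECOYK"
        assert top3(pd.concat([df, decoy], ignore_index=True),
                    "P1", "bean_1") == pytest.approx(8.0)

    def test_other_modifications_excluded(self):
        df = peptide_rows([10, 8, 6])
        phospho = peptide_rows([500], Modifications="Phospho (STY)")
        phospho.loc[0, "Sequence"] = "PHOSK"
        assert top3(pd.concat([df, phospho], ignore_index=True),
                    "P1", "bean_1") == pytest.approx(8.0)

    def test_strict_mode_requires_three_peptides(self):
        df = peptide_rows([10, 8])
        with pytest.raises(ValueError, match="3 required"):
            top3(df, "P1", "bean_1", strict=True)
        assert top3(df, "P1", "bean_1", strict=False) == pytest.approx(9.0)

    @given(perm=st.permutations(range(5)))
    def test_permutation_invariance(self, perm):
        df = peptide_rows([10, 8, 6, 4, 2]).iloc[list(perm)].reset_index(
            drop=True)
        assert top3(df, "P1", "bean_1") == pytest.approx(8.0)


class TestAbsoluteAbundance:
    def test_unity_ratio_returns_spike(self):
        assert absolute_abundance(100.0, 100.0) == pytest.approx(12.5)

    def test_ratio_two_returns_double_spike(self):
        assert absolute_abundance(200.0, 100.0) == pytest.approx(25.0)

    def test_zero_hi3_signal_rejected(self):
        with pytest.raises(ValueError):
            absolute_abundance(10.0, 0.0)


class TestCopyNumbers:
    def test_bean_cascade_arithmetic(self):
        row = copy_numbers(1.0, QuantConstants(), "bean")
        assert row["C_p"] == pytest.approx(6.0221413e8)
        assert row["per_bacteroid"] == pytest.approx(500.8, abs=0.05)

    def test_zero_abundance_gives_zero_row(self):
        row = copy_numbers(0.0, QuantConstants(), "pea")
        assert all(v == 0.0 for v in row.values())

    @given(a_b=st.floats(1e-6, 1e3))
    def test_volume_identity_every_row(self, a_b):
        k = QuantConstants()
        for host in ("bean", "pea"):
            row = copy_numbers(a_b, k, host)
            assert row["per_bacteroid_volume"] * k.b_vol[host] == \
                pytest.approx(row["per_bacteroid"], rel=1e-12)

    def test_unknown_host_rejected(self):
        with pytest.raises(ValueError, match="unknown host"):
            copy_numbers(1.0, QuantConstants(), "soybean")


class TestEndToEndQuant:
    def test_zero_noise_recovers_planted_copies(self, gt0):
        pep = generate_peptide_table(gt0, n_reps=2, seed=0, intensity_cv=0.0)
        q = quant.quantify(pep)
        for protein, (bean_copies, pea_copies) in \
                gt0.protein_copies.items():
            got = q.query("protein == @protein and host == 'bean'")
            assert got["per_bacteroid"].mean() == pytest.approx(
                bean_copies, rel=1e-3)

    def test_planted_fold_change_recovered_with_noise(self, gt):
        pep = generate_peptide_table(gt, n_reps=3, seed=42, intensity_cv=0.10)
        fc = fold_change_table(quant.quantify(pep))
        # NifH planted at pea/bean = 5.49; CV 10%, n = 3 per group
        assert fc.loc["NifH", "fc_per_bacteroid"] == pytest.approx(
            5.49, rel=0.20)

    def test_scale_identities_hold_for_every_protein(self, gt):
        pep = generate_peptide_table(gt, n_reps=3, seed=7, intensity_cv=0.10)
        fc = fold_change_table(quant.quantify(pep))
        k = QuantConstants()
        ratio = k.b_vol["bean"] / k.b_vol["pea"]
        assert np.allclose(fc["fc_per_bacteroid_volume"],
                           fc["fc_per_bacteroid"] * ratio, rtol=1e-9)
        ratio_p = k.b_p["bean"] / k.b_p["pea"]
        assert np.allclose(fc["fc_per_unit_protein"],
                           fc["fc_per_bacteroid"] * ratio_p, rtol=1e-9)

    def test_identical_groups_fold_one_p_one(self):
        q = pd.DataFrame([
            {"protein": "P", "sample": s, "host": h, "per_bacteroid": 100.0,
             "per_bacteroid_volume": 10.0, "per_nodule": 1.0,
             "per_nodule_volume": 1.0, "per_unit_protein": 1.0}
            for h in ("bean", "pea") for s in (f"{h}_1", f"{h}_2")])
        fc = fold_change_table(q)
        assert fc.loc["P", "fc_per_bacteroid"] == pytest.approx(1.0)
        assert fc.loc["P", "p_value"] == pytest.approx(1.0)


class TestProteomeMassRank:
    def test_small_example(self):
        _, n = proteome_mass_rank([30, 25, 10, 20, 15])
        assert n == 2

    def test_uniform_distribution(self):
        _, n = proteome_mass_rank([1.0] * 100)
        assert n == 50

    @pytest.mark.parametrize("n_half,n_proteins", [(18, 197), (30, 184)])
    def test_planted_skew_recovered(self, n_half, n_proteins):
        fractions = generate_mass_fractions(n_proteins, n_half)
        _, n = proteome_mass_rank(fractions)
        assert n == n_half


class TestDistributionAndCorrelation:
    def test_identical_samples(self):
        d, p = distribution_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = distribution_compare(np.arange(20), np.arange(100, 120))
        assert d == 1.0

    def test_different_skews_detected_at_study_scale(self):
        # two planted lognormal proteomes with different sigma, n ≈ 190
        rng = np.random.default_rng(0)
        a = rng.lognormal(0.0, 0.8, 190)
        b = rng.lognormal(0.0, 1.6, 190)
        _, p = distribution_compare(a / a.sum(), b / b.sum())
        assert p < 0.05

    def test_perfect_proportionality(self):
        r, r2 = rna_protein_correlation([1, 2, 3, 4.0], [2, 4, 6, 8.0])
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_anti_proportional(self):
        r, _ = rna_protein_correlation([1, 2, 3.0], [6, 4, 2.0])
        assert r == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        from nodusym.simulate import generate_rna_protein_pairs
        pairs = generate_rna_protein_pairs(197, r=0.84, seed=2)
        r, _ = rna_protein_correlation(pairs["protein_fg_per_bacteroid"],
                                       pairs["rna_norm_counts"], log=True)
        # CI half-width for r = 0.84 at n = 197 is about 0.04
        assert r == pytest.approx(0.84, abs=0.08)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rna_protein_correlation([1.0, 1.0, 1.0], [1, 2, 3])
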