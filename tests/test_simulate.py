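"""Generator contracts: determinism, degenerate cases, parameter recovery
and cross-table internal consistency."""

import numpy as np
import pandas as pd
import pytest

from nodusym import census, geometry
from nodusym.simulate import (GroundTruth, Param, generate_bundle,
                              generate_peptide_table, generate_plants,
                              generate_sections, generate_segmentation)


class TestParam:
    def test_from_se_round_trip(self):
        p = Param.from_se(610.0, 50.2, 11)
        assert p.cv == pytest.approx(50.2 * np.sqrt(11) / 610.0)

    def test_zero_cv_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert np.all(Param(5.0, 0.0).sample(rng, 10) == 5.0)

    def test_lognormal_mean_is_unbiased(self):
        rng = np.random.default_rng(1)
        x = Param(10.0, 0.3).sample(rng, 200_000)
        assert x.mean() == pytest.approx(10.0, rel=0.01)
        assert x.std() / x.mean() == pytest.approx(0.3, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Param(-1.0)
        with pytest.raises(ValueError):
            Param(1.0, cv=-0.1)


class TestDeterminism:
    def test_identical_seed_gives_identical_bundle(self, gt):
        b1 = generate_bundle(gt, seed=9, n_plants=4, n_nodules=3,
                             n_bacteroids=20, n_packing=3)
        b2 = generate_bundle(gt, seed=9, n_plants=4, n_nodules=3,
                             n_bacteroids=20, n_packing=3)
        for name, df in b1.tables().items():
            pd.testing.assert_frame_equal(df, b2.tables()[name])

    def test_different_seeds_differ(self, gt):
        p1 = generate_plants(gt, 5, seed=1)
        p2 = generate_plants(gt, 5, seed=2)
        assert not p1["shoot_dry_mass_mg"].equals(p2["shoot_dry_mass_mg"])

    def test_tsv_write_is_byte_identical(self, gt, tmp_path):
        for i, sub in enumerate(("a", "b")):
            generate_bundle(gt, seed=3, n_plants=3, n_nodules=2,
                            n_bacteroids=10, n_packing=2).write(tmp_path / sub)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestPlants:
    def test_zero_noise_rows_equal_means(self, gt0):
        plants = generate_plants(gt0, 3, seed=0).query("host == 'bean'")
        assert np.all(plants["shoot_dry_mass_mg"] == 610.0)
        assert np.all(plants["nodule_count"] == 125)

    def test_law_of_large_numbers_recovery(self, gt):
        plants = generate_plants(gt, 1000, seed=4).query("host == 'bean'")
        assert plants["shoot_dry_mass_mg"].mean() == pytest.approx(
            610.0, rel=0.02)

    def test_minimum_cohort_size_enforced(self, gt):
        with pytest.raises(ValueError):
            generate_plants(gt, 1, seed=0)


class TestSections:
    def test_zero_noise_bean_round_trip(self, gt0):
        secs = generate_sections(gt0, 1, seed=0)
        v = geometry.bean_volumes_table(secs["bean"]).iloc[0]
        assert v["V_n"] == pytest.approx(6.07, rel=1e-6)

    def test_zero_noise_pea_round_trip(self, gt0):
        secs = generate_sections(gt0, 1, seed=0)
        v = geometry.pea_volumes_table(secs["pea"]).iloc[0]
        assert v["V_n"] == pytest.approx(4.61, rel=1e-6)

    def test_colonization_density_encoded_in_areas(self, gt0):
        secs = generate_sections(gt0, 2, seed=0)
        for host in ("bean", "pea"):
            df = secs[host]
            f_c = gt0.host(host).colonization_density.mean
            assert np.allclose(df["A_i"] / df["A_iz"], f_c)

    def test_infected_fraction_encoded(self, gt0):
        # V_i / V_n equals infected_fraction by construction at zero noise
        secs = generate_sections(gt0, 1, seed=0)
        v = geometry.bean_volumes_table(secs["bean"]).iloc[0]
        assert v["V_i"] / v["V_n"] == pytest.approx(0.242, rel=1e-6)


class TestSegmentation:
    def test_zero_noise_volumes_exact(self, gt0):
        seg = generate_segmentation(gt0, 5, seed=0)
        assert np.all(seg.query("host == 'bean'")["volume_um3"] == 0.93)
        assert np.all(seg.query("host == 'pea'")["volume_um3"] == 4.50)

    def test_all_records_physically_valid(self, gt):
        seg = generate_segmentation(gt, 300, seed=8)
        census.validate_segmentation(seg)  # raises on violation


class TestPeptideTable:
    def test_maxquant_dialect_columns(self, gt):
        pep = generate_peptide_table(gt, n_reps=2, seed=0)
        for col in ("Sequence", "Modifications", "Missed cleavages",
                    "Proteins", "Unique", "Intensity bean_1",
                    "Intensity pea_2"):
            assert col in pep.columns

    def test_contains_decoys_and_split_oxidation(self, gt):
        pep = generate_peptide_table(gt, n_reps=1, seed=0)
        assert (pep["Missed cleavages"] > 0).any()
        assert (~pep["Modifications"].isin(
            ["Unmodified", "Oxidation (M)"])).any()
        assert (pep["Modifications"] == "Oxidation (M)").any()

    def test_minimum_peptides_enforced(self, gt):
        with pytest.raises(ValueError):
            generate_peptide_table(gt, n_peptides=2, seed=0)


class TestInternalConsistency:
    def test_bacteroids_per_nodule_matches_ground_truth_implied(self, gt0):
        """Zero-noise pipeline count equals the count implied by
        infected_fraction × packing × V_n / bacteroid volume to <1%."""
        bundle = generate_bundle(gt0, seed=0, n_plants=2, n_nodules=2,
                                 n_bacteroids=5, n_packing=2)
        for host in ("bean", "pea"):
            t = gt0.host(host)
            table = (geometry.bean_volumes_table(bundle.bean_section_table)
                     if host == "bean" else
                     geometry.pea_volumes_table(bundle.pea_section_table))
            v_i = table["V_i"].mean()
            packing, _ = census.packing_fraction(
                bundle.packing_table.query("host == @host"))
            count = census.bacteroids_per_nodule(
                census.total_bacteroid_volume(v_i, packing),
                t.bacteroid_volume_um3.mean)
            implied = (t.infected_fraction.mean * t.packing_fraction.mean
                       * t.nodule_volume_mm3.mean * 1e9
                       / t.bacteroid_volume_um3.mean)
            assert count == pytest.approx(implied, rel=0.01)

    def test_parameter_recovery_within_three_se(self, gt):
        """With 500 plants, pipeline estimates of plant-scale means lie
        within 3 standard errors of the generator truth."""
        plants = generate_plants(gt, 500, seed=6)
        for host in ("bean", "pea"):
            t = gt.host(host)
            hp = plants.query("host == @host")
            for column, param in [
                    ("shoot_dry_mass_mg", t.shoot_dry_mass_mg),
                    ("plant_nodule_dry_mass_mg", t.plant_nodule_dry_mass_mg),
                    ("plant_nodule_volume_mm3", t.plant_nodule_volume_mm3)]:
                se = hp[column].std(ddof=1) / np.sqrt(len(hp))
                assert abs(hp[column].mean() - param.mean) < 3 * se
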