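"""Loading, validation and pooling of experiment tables."""

import numpy as np
import pandas as pd
import pytest

from mixtraits import experiment_model as em


def _write_minimal_experiment(tmp_path):
    design = pd.DataFrame(
        {
            "block": ["B1"],
            "pot": ["P01"],
            "fertilization": ["F-"],
            "irrigation": ["W+"],
            "culture": ["mono"],
            "role": ["factorial"],
        }
    )
    plants = pd.DataFrame(
        {
            "pot": ["P01"] * 3,
            "plant": [1, 2, 3],
            "genotype": ["Loden"] * 3,
            "harvest": ["final"] * 3,
            "m_leaf": [1.0, 2.0, 3.0],
            "m_shoot": [1.5, 2.5, 3.5],
            "m_root": [0.5, 1.0, 1.5],
            "m_cutting": [3.0, 3.0, 3.0],
            "a_leaf": [0.02, 0.04, 0.06],
            "n_leaves": [10, 20, 30],
            "shoot_height": [0.3, 0.4, 0.5],
            "shoot_diameter": [4.0, 5.0, 6.0],
        }
    )
    nitrogen = pd.DataFrame(
        {
            "pot": ["P01"],
            "genotype": ["Loden"],
            "harvest": ["final"],
            "N_leaf": [0.06],
            "N_shoot": [0.03],
            "N_root": [0.015],
            "N_cutting": [0.05],
        }
    )
    paths = {
        "plants": tmp_path / "plants.csv",
        "nitrogen": tmp_path / "nitrogen.csv",
        "design": tmp_path / "design.csv",
    }
    plants.to_csv(paths["plants"], index=False)
    nitrogen.to_csv(paths["nitrogen"], index=False)
    design.to_csv(paths["design"], index=False)
    return paths


class TestLoadTables:
    def test_well_formed_csv_loads_all_rows(self, tmp_path):
        paths = _write_minimal_experiment(tmp_path)
        plants, samples = em.load_tables(paths["plants"], paths["nitrogen"], paths["design"])
        assert len(plants) == 3
        assert len(samples) == 1

    def test_negative_mass_is_rejected_with_row_context(self, tmp_path):
        paths = _write_minimal_experiment(tmp_path)
        plants = pd.read_csv(paths["plants"])
        plants.loc[1, "m_leaf"] = -1.0
        plants.to_csv(paths["plants"], index=False)
        with pytest.raises(em.ValidationError, match=r"row 1.*m_leaf"):
            em.load_tables(paths["plants"], paths["nitrogen"], paths["design"])

    def test_missing_column_names_the_column(self, tmp_path):
        paths = _write_minimal_experiment(tmp_path)
        plants = pd.read_csv(paths["plants"]).drop(columns=["m_shoot"])
        plants.to_csv(paths["plants"], index=False)
        with pytest.raises(em.SchemaError, match="m_shoot"):
            em.load_tables(paths["plants"], paths["nitrogen"], paths["design"])

    def test_orphan_plant_pot_is_rejected(self, tmp_path):
        paths = _write_minimal_experiment(tmp_path)
        plants = pd.read_csv(paths["plants"])
        plants.loc[2, "pot"] = "P99"
        plants.to_csv(paths["plants"], index=False)
        with pytest.raises(em.ValidationError, match="P99"):
            em.load_tables(paths["plants"], paths["nitrogen"], paths["design"])

    def test_round_trip_is_identity_on_generated_experiment(self, tmp_path, experiment):
        paths = em.write_tables(experiment.plants, experiment.nitrogen, experiment.design, tmp_path)
        plants = em.read_plants(paths["plants"])
        nitrogen = em.read_nitrogen(paths["nitrogen"])
        design = em.read_design(paths["design"])
        pd.testing.assert_frame_equal(plants, experiment.plants[em.PLANT_COLUMNS])
        pd.testing.assert_frame_equal(nitrogen, experiment.nitrogen[em.NITROGEN_COLUMNS])
        pd.testing.assert_frame_equal(design, experiment.design[em.DESIGN_COLUMNS])


class TestPooling:
    def test_masses_sum_exactly_within_group(self, experiment, samples):
        plants = experiment.plants
        for (pot, genotype, harvest), group in plants.groupby(["pot", "genotype", "harvest"]):
            row = samples[
                (samples["pot"] == pot)
                & (samples["genotype"] == genotype)
                & (samples["harvest"] == harvest)
            ].iloc[0]
            assert row["m_leaf"] == pytest.approx(group["m_leaf"].sum(), rel=1e-12)
            assert row["m_total"] == row["m_leaf"] + row["m_shoot"] + row["m_root"]
            assert row["AGB"] == row["m_leaf"] + row["m_shoot"]

    def test_group_sizes_match_planting(self, samples):
        final = samples[(samples["harvest"] == "final")]
        assert (final.loc[final["culture"] == "mono", "n_plants"] == 6).all()
        assert (final.loc[final["culture"] == "mix", "n_plants"] == 3).all()

    def test_plant_n_is_sum_of_organ_pools(self, samples):
        np.testing.assert_allclose(
            samples["N_plant"], samples[["N_leaf", "N_shoot", "N_root"]].sum(axis=1), rtol=0
        )

    def test_per_plant_means_retained(self, samples):
        np.testing.assert_allclose(samples["mean_m_leaf"] * samples["n_plants"], samples["m_leaf"])


class TestValidateDesign:
    def test_canonical_design_is_clean(self, samples):
        report = em.validate_design(samples)
        assert report.n_pots == 48
        assert report.n_plants == 288
        assert report.ok

    def test_unbalanced_mix_pot_is_flagged(self, experiment):
        plants = experiment.plants.copy()
        mix_pot = "P03"  # third pot of block 1 is the first mixture pot
        idx = plants[(plants["pot"] == mix_pot) & (plants["genotype"] == "Tora")].index[0]
        plants.loc[idx, "genotype"] = "Loden"
        nitrogen = (
            plants.groupby(["pot", "genotype", "harvest"], as_index=False)
            .agg(m=("m_leaf", "sum"))
            .drop(columns="m")
        )
        for col in ("N_leaf", "N_shoot", "N_root", "N_cutting"):
            nitrogen[col] = 0.01
        samples = em.pool_to_genotype_pot(plants, nitrogen, experiment.design)
        report = em.validate_design(samples)
        assert any("50:50" in v and mix_pot in v for v in report.violations)

    def test_missing_block_reports_reduced_pot_count(self, experiment):
        design = experiment.design[experiment.design["block"] != "B4"]
        plants = experiment.plants[experiment.plants["pot"].isin(design["pot"])]
        nitrogen = experiment.nitrogen[experiment.nitrogen["pot"].isin(design["pot"])]
        samples = em.pool_to_genotype_pot(plants, nitrogen, design)
        report = em.validate_design(samples)
        assert report.n_pots == 36
        assert report.n_plants == 216


class TestIrrigationPooling:
    def test_irrigation_becomes_replication(self, samples):
        pooled = em.pool_irrigation_replicates(samples)
        assert "irrigation" not in pooled.columns
        assert "replicate" in pooled.columns
        final = pooled[(pooled["harvest"] == "final") & (pooled["culture"] == "mono")]
        counts = final.groupby(["fertilization", "genotype"])["pot"].nunique()
        assert (counts == 8).all()

    def test_pass_through_without_irrigation_column(self, samples):
        once = em.pool_irrigation_replicates(samples)
        twice = em.pool_irrigation_replicates(once)
        pd.testing.assert_frame_equal(once, twice)


class TestBroadcastInitial:
    def test_initial_means_scale_with_group_size(self, samples):
        paired = em.broadcast_initial(samples)
        initial = samples[samples["harvest"] == "initial"]
        per_plant = (
            initial.set_index("genotype")["m_leaf"] / initial.set_index("genotype")["n_plants"]
        )
        for _, row in paired.head(20).iterrows():
            expected = per_plant[row["genotype"]] * row["n_plants"]
            assert row["m_leaf_init"] == pytest.approx(expected, rel=1e-12)

    def test_delta_t_matches_harvest_schedule(self, samples):
        paired = em.broadcast_initial(samples)
        assert np.allclose(paired["delta_t"], (120 - 34) / 7.0)

    def test_missing_initial_harvest_is_an_error(self, samples):
        with pytest.raises(em.ValidationError, match="initial"):
            em.broadcast_initial(samples[samples["harvest"] == "final"])

    def test_harvest_pair_requires_positive_delta_t(self):
        with pytest.raises(em.ValidationError):
            em.HarvestPair(initial={}, final={}, delta_t=0.0)
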