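"""Synthetic experiment generator: design counts, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from mixtraits import experiment_model as em
from mixtraits import synthetic_data as sd
from mixtraits.diversity_effects import partition_from_samples


class TestDesignInstantiation:
    def test_default_counts(self, experiment):
        design = experiment.design
        factorial = design[design["role"] == "factorial"]
        assert len(factorial) == 48
        final_plants = experiment.plants[experiment.plants["harvest"] == "final"]
        assert len(final_plants) == 288
        initial_plants = experiment.plants[experiment.plants["harvest"] == "initial"]
        assert len(initial_plants) == 12  # one pot of six plants per genotype

    def test_blocks_and_cells(self, experiment):
        factorial = experiment.design[experiment.design["role"] == "factorial"]
        assert factorial.groupby("block")["pot"].nunique().eq(12).all()
        cells = factorial.groupby(["fertilization", "irrigation", "culture"])["pot"].count()
        assert cells.loc[("F+", "W+", "mono")] == 8  # 2 mono pots x 4 blocks
        assert cells.loc[("F+", "W+", "mix")] == 4

    def test_dose_schedule_ratio(self):
        cfg = sd.GeneratorConfig()
        assert cfg.weekly_n_dose_mg["F+"] / cfg.weekly_n_dose_mg["F-"] == pytest.approx(120 / 20)


class TestDeterminism:
    def test_identical_seed_gives_identical_tables(self):
        cfg = sd.GeneratorConfig()
        first = sd.generate_experiment(cfg, seed=99)
        second = sd.generate_experiment(cfg, seed=99)
        pd.testing.assert_frame_equal(first.plants, second.plants)
        pd.testing.assert_frame_equal(first.nitrogen, second.nitrogen)
        pd.testing.assert_frame_equal(first.design, second.design)

    def test_different_seeds_differ(self):
        cfg = sd.GeneratorConfig()
        first = sd.generate_experiment(cfg, seed=1)
        second = sd.generate_experiment(cfg, seed=2)
        assert not first.plants["m_leaf"].equals(second.plants["m_leaf"])

    def test_byte_identical_csv_output(self, tmp_path):
        cfg = sd.GeneratorConfig()
        for run in ("a", "b"):
            exp = sd.generate_experiment(cfg, seed=7)
            em.write_tables(exp.plants, exp.nitrogen, exp.design, tmp_path / run)
        for name in ("plants.csv", "nitrogen.csv", "design.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestNoiseFreeTruth:
    def test_all_plants_in_a_cell_identical(self, noise_free_experiment):
        plants = noise_free_experiment.plants
        final = plants[plants["harvest"] == "final"]
        merged = final.merge(noise_free_experiment.design, on="pot")
        spread = merged.groupby(["genotype", "fertilization", "culture"])["m_leaf"].agg(["min", "max"])
        np.testing.assert_allclose(spread["min"], spread["max"], rtol=1e-12)

    def test_pipeline_traits_equal_closed_form_truth(self, noise_free_experiment, noise_free_samples):
        from mixtraits.growth_traits import compute_growth_traits
        from mixtraits.nitrogen_economy import compute_nitrogen_traits

        truth = noise_free_experiment.truth.cells.set_index(["genotype", "fertilization", "culture"])
        traits = pd.concat(
            [
                compute_growth_traits(noise_free_experiment.plants, noise_free_samples),
                compute_nitrogen_traits(noise_free_samples),
            ],
            ignore_index=True,
        )
        checked = 0
        for trait in ("SLA", "LAR", "LMR", "RMF", "root_shoot", "SRL", "SRA",
                      "RGR", "LN/LA", "LNP", "LAP", "U_N", "E_N,y", "eta"):
            sub = traits[(traits["trait"] == trait) & (traits["level"] != "community")]
            expected = truth.loc[
                pd.MultiIndex.from_frame(sub[["genotype", "fertilization", "culture"]]), trait
            ].to_numpy()
            np.testing.assert_allclose(sub["value"], expected, rtol=1e-9)
            checked += len(sub)
        assert checked == 14 * 64

    def test_partition_on_noise_free_data_equals_truth(self, noise_free_experiment, noise_free_samples):
        pooled = em.pool_irrigation_replicates(noise_free_samples)
        _, summaries = partition_from_samples(pooled, n=10, seed=0)
        for fert, summary in summaries.items():
            expected = noise_free_experiment.truth.partition[fert]
            assert summary.means["net"] == pytest.approx(expected.net, rel=1e-9, abs=1e-12)
            assert summary.means["complementarity"] == pytest.approx(
                expected.complementarity, rel=1e-9, abs=1e-12
            )
            assert summary.means["selection"] == pytest.approx(expected.selection, rel=1e-9, abs=1e-12)


class TestTruthPartition:
    def test_null_configuration_gives_zero_effects(self):
        truth = sd.truth_partition(sd.GeneratorConfig.null())
        for result in truth.values():
            assert result.net == pytest.approx(0.0, abs=1e-12)
            assert result.complementarity == pytest.approx(0.0, abs=1e-12)
            assert result.selection == pytest.approx(0.0, abs=1e-12)

    def test_exchangeable_genotypes_put_everything_in_complementarity(self):
        truth = sd.truth_partition(sd.GeneratorConfig.complementarity_only(effect=1.35))
        for result in truth.values():
            assert result.selection == pytest.approx(0.0, abs=1e-12)
            assert result.complementarity == pytest.approx(result.net, rel=1e-12)
        # F-: per-plant AGB 2.0 g, six plants in monoculture, 35% overyield
        assert truth["F-"].complementarity == pytest.approx(2 * 0.175 * 12.0, rel=1e-12)

    def test_asymmetric_config_matches_partition_of_expected_yields(self):
        cfg = sd.GeneratorConfig()
        truth = sd.truth_partition(cfg)
        cells = sd.expected_cells(cfg).set_index(["genotype", "fertilization", "culture"])
        from mixtraits.diversity_effects import MonoMixCombination, partition_additive

        for fert in ("F+", "F-"):
            combo = MonoMixCombination(
                cfg.genotypes,
                mono_yields=[cells.loc[(g, fert, "mono"), "pot_yield"] for g in cfg.genotypes],
                mix_yields=[cells.loc[(g, fert, "mix"), "pot_yield"] for g in cfg.genotypes],
            )
            result = partition_additive(combo)
            assert truth[fert].net == pytest.approx(result.net, rel=1e-12)
            assert truth[fert].complementarity == pytest.approx(result.complementarity, rel=1e-12)
            assert truth[fert].selection == pytest.approx(result.selection, rel=1e-12)

    def test_truth_round_trips_through_json(self, tmp_path, experiment):
        path = tmp_path / "truth.json"
        experiment.truth.to_json(path)
        loaded = sd.SyntheticTruth.from_json(path)
        for fert in ("F+", "F-"):
            assert loaded.partition[fert].net == pytest.approx(experiment.truth.partition[fert].net)
        pd.testing.assert_frame_equal(
            loaded.cells[experiment.truth.cells.columns], experiment.truth.cells
        )


class TestConfigValidation:
    def test_bad_fields_are_listed(self):
        cfg = sd.GeneratorConfig(sigma_plant=-1.0, initial_fraction=2.0)
        with pytest.raises(sd.ConfigError) as err:
            cfg.validate()
        assert "sigma_plant" in str(err.value)
        assert "initial_fraction" in str(err.value)

    def test_zero_dose_rejected(self):
        cfg = sd.GeneratorConfig(weekly_n_dose_mg={"F+": 8.4, "F-": 0.0})
        with pytest.raises(sd.ConfigError, match="dose"):
            cfg.validate()


class TestRecovery:
    def test_report_shape_and_columns(self):
        report = sd.recovery_experiment(sd.GeneratorConfig.null(), n_datasets=3, seed=1, n_combinations=20)
        assert len(report.estimates) == 6  # 3 datasets x 2 fertilization levels
        assert {"net", "complementarity", "selection", "p_net"} <= set(report.estimates.columns)
        summary = report.summary()
        assert set(summary["effect"]) == {"net", "complementarity", "selection"}

    def test_noise_widens_complementarity_estimates(self):
        quiet = sd.recovery_experiment(
            sd.GeneratorConfig.complementarity_only(sigma_plant=0.1, pot_sd=0.04),
            n_datasets=30, seed=21, n_combinations=60,
        )
        loud = sd.recovery_experiment(
            sd.GeneratorConfig.complementarity_only(sigma_plant=0.4, pot_sd=0.16),
            n_datasets=30, seed=21, n_combinations=60,
        )
        for fert in ("F+", "F-"):
            sd_quiet = quiet.estimates.query("fertilization == @fert")["complementarity"].std()
            sd_loud = loud.estimates.query("fertilization == @fert")["complementarity"].std()
            assert sd_loud > sd_quiet
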