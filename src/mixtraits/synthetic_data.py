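"""Seeded generator for complete synthetic monoculture/mixture experiments.

The generator emulates the statistical structure of a two-genotype willow
container experiment: 2 fertilization x 2 irrigation x {2 monocultures,
1 mixture} x 4 blocks = 48 pots of six plants each (288 plants), plus one
extra pot per genotype destructively harvested at the start of the
fertilization period.  Fertilizer is applied weekly (1.4 mg N per plant at
F-, 8.4 at F+ — the 20 vs 120 kg N ha^-1 yr^-1 contrast), harvests fall at
days 34 and 120 after planting.

The noise model is deliberately simple: plant size is lognormal around the
cell mean with a shared pot-level random effect and an organ-level jitter,
all on the log scale and mean-corrected so that expectations equal the
configured cell means exactly; genotype-pot N concentrations get an
independent lognormal jitter.  Irrigation is generated as a pure replicate
label with no effect.  Mixture responses are injected as per-genotype
multiplicative effects on aboveground organ masses (optionally plus an
additive per-genotype pot-level yield shift), so the implied ground-truth
diversity-effect partition is available in closed form
(:func:`truth_partition`) and every pipeline stage can be checked against
known truth (:func:`recovery_experiment`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from mixtraits.diversity_effects import (
    EFFECT_NAMES,
    PartitionResult,
    partition_from_samples,
)
from mixtraits.experiment_model import (
    DEFAULT_HARVEST_DAYS,
    PLANTS_PER_POT,
    pool_irrigation_replicates,
    pool_to_genotype_pot,
)
from mixtraits.growth_traits import N_MOLAR_MASS
from mixtraits.nitrogen_economy import logarithmic_mean


class ConfigError(ValueError):
    """The generator configuration violates one or more field constraints."""


def _default_baseline_mass():
    # per-plant final-harvest organ dry masses (g) at F-, monoculture
    return {
        "Loden": {"leaf": 1.1, "shoot": 1.3, "root": 0.9},
        "Tora": {"leaf": 0.5, "shoot": 0.8, "root": 0.5},
    }


def _default_baseline_n_conc():
    # g N per g dry mass at F-; the N-acquisitive genotype runs richer
    return {
        "Loden": {"leaf": 0.007, "shoot": 0.0035, "root": 0.005},
        "Tora": {"leaf": 0.014, "shoot": 0.006, "root": 0.007},
    }


def _default_culture_effects():
    # multiplicative mixture response of aboveground organ masses:
    # at F- the smaller-monoculture genotype overyields in mixture
    # (complementarity > 0, selection < 0); at F+ both underyield with the
    # larger-monoculture genotype hit harder (complementarity < 0,
    # selection weakly < 0)
    return {
        "F-": {"Loden": 0.84, "Tora": 1.26},
        "F+": {"Loden": 0.78, "Tora": 0.88},
    }


def _default_shift():
    return {
        "F-": {"Loden": 0.0, "Tora": 0.0},
        "F+": {"Loden": 0.0, "Tora": 0.0},
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic experiment.

    Masses are grams per plant, N concentrations g N per g dry mass, doses
    mg N per plant per week, noise standard deviations on the natural-log
    scale.
    """

    n_blocks: int = 4
    genotypes: tuple[str, str] = ("Loden", "Tora")
    baseline_mass: dict = field(default_factory=_default_baseline_mass)
    fertilization_mass_multiplier: dict = field(
        default_factory=lambda: {"leaf": 2.5, "shoot": 2.5, "root": 1.6}
    )
    baseline_n_conc: dict = field(default_factory=_default_baseline_n_conc)
    fertilization_conc_multiplier: float = 1.5
    cutting_mass: dict = field(default_factory=lambda: {"Loden": 3.0, "Tora": 3.0})
    cutting_n_conc: dict = field(default_factory=lambda: {"Loden": 0.0055, "Tora": 0.0040})
    sla_m2_per_kg: dict = field(default_factory=lambda: {"Loden": 18.0, "Tora": 13.0})
    srl_m_per_g: float = 40.0
    sra_cm2_per_g: float = 250.0
    culture_effects: dict = field(default_factory=_default_culture_effects)
    complementarity_shift: dict = field(default_factory=_default_shift)
    initial_fraction: float = 0.03
    initial_n_conc: dict = field(
        default_factory=lambda: {"leaf": 0.020, "shoot": 0.010, "root": 0.012}
    )
    sigma_plant: float = 0.30
    sigma_organ: float = 0.10
    pot_sd: float = 0.10
    conc_sd: float = 0.05
    cutting_sd: float = 0.08
    harvest_days: tuple[int, int] = DEFAULT_HARVEST_DAYS
    weekly_n_dose_mg: dict = field(default_factory=lambda: {"F+": 8.4, "F-": 1.4})
    fertilization_weeks: int = 13
    seed: int = 17

    # ------------------------------------------------------------------
    def validate(self) -> None:
        bad: list[str] = []
        if self.n_blocks < 1:
            bad.append("n_blocks must be >= 1")
        if len(self.genotypes) != 2:
            bad.append("exactly two genotypes are supported")
        for g in self.genotypes:
            masses = self.baseline_mass.get(g, {})
            if any(masses.get(o, 0) <= 0 for o in ("leaf", "shoot", "root")):
                bad.append(f"baseline_mass[{g}] must be positive for leaf, shoot and root")
            concs = self.baseline_n_conc.get(g, {})
            if any(concs.get(o, 0) <= 0 for o in ("leaf", "shoot", "root")):
                bad.append(f"baseline_n_conc[{g}] must be positive for leaf, shoot and root")
            if self.cutting_mass.get(g, 0) <= 0:
                bad.append(f"cutting_mass[{g}] must be positive")
            if self.cutting_n_conc.get(g, 0) <= 0:
                bad.append(f"cutting_n_conc[{g}] must be positive")
            if self.sla_m2_per_kg.get(g, 0) <= 0:
                bad.append(f"sla_m2_per_kg[{g}] must be positive")
        if any(v <= 0 for v in self.fertilization_mass_multiplier.values()):
            bad.append("fertilization_mass_multiplier values must be positive")
        if self.fertilization_conc_multiplier <= 0:
            bad.append("fertilization_conc_multiplier must be positive")
        for fert, per_geno in self.culture_effects.items():
            if any(v <= 0 for v in per_geno.values()):
                bad.append(f"culture_effects[{fert}] values must be positive")
        for name in ("sigma_plant", "sigma_organ", "pot_sd", "conc_sd", "cutting_sd"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be non-negative")
        if not 0 < self.initial_fraction < 1:
            bad.append("initial_fraction must lie in (0, 1)")
        if any(d <= 0 for d in self.weekly_n_dose_mg.values()):
            bad.append("weekly_n_dose_mg values must be positive")
        if self.fertilization_weeks <= 0:
            bad.append("fertilization_weeks must be positive")
        if not self.harvest_days[1] > self.harvest_days[0] > 0:
            bad.append("harvest_days must be increasing and positive")
        if bad:
            raise ConfigError("invalid generator configuration: " + "; ".join(bad))

    def replace(self, **overrides) -> "GeneratorConfig":
        return dataclasses.replace(self, **overrides)

    # -- canned study conditions ---------------------------------------
    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """No injected mixture response: all diversity effects are zero."""
        cfg = cls(
            culture_effects={"F-": {"Loden": 1.0, "Tora": 1.0}, "F+": {"Loden": 1.0, "Tora": 1.0}},
            complementarity_shift=_default_shift(),
        )
        return cfg.replace(**overrides) if overrides else cfg

    @classmethod
    def complementarity_only(
        cls,
        effect: float = 1.35,
        sigma_plant: float = 0.20,
        pot_sd: float = 0.08,
        **overrides,
    ) -> "GeneratorConfig":
        """Exchangeable genotypes with a shared mixture overyield.

        Both genotypes get identical baselines and the same multiplicative
        mixture response, so the true selection effect is exactly zero and
        the whole net effect is complementarity.
        """
        shared_mass = {"leaf": 0.9, "shoot": 1.1, "root": 0.8}
        shared_conc = {"leaf": 0.009, "shoot": 0.004, "root": 0.005}
        cfg = cls(
            baseline_mass={"Loden": dict(shared_mass), "Tora": dict(shared_mass)},
            baseline_n_conc={"Loden": dict(shared_conc), "Tora": dict(shared_conc)},
            cutting_mass={"Loden": 3.0, "Tora": 3.0},
            cutting_n_conc={"Loden": 0.005, "Tora": 0.005},
            sla_m2_per_kg={"Loden": 15.0, "Tora": 15.0},
            culture_effects={
                "F-": {"Loden": effect, "Tora": effect},
                "F+": {"Loden": effect, "Tora": effect},
            },
            complementarity_shift=_default_shift(),
            sigma_plant=sigma_plant,
            pot_sd=pot_sd,
        )
        return cfg.replace(**overrides) if overrides else cfg


# ----------------------------------------------------------------------
# expected (noise-free) cell values


def _organ_means(cfg: GeneratorConfig, genotype: str, fertilization: str, culture: str) -> dict:
    """Expected per-plant organ masses (g) for one design cell."""
    base = cfg.baseline_mass[genotype]
    fmult = cfg.fertilization_mass_multiplier
    means = {
        organ: base[organ] * (fmult[organ] if fertilization == "F+" else 1.0)
        for organ in ("leaf", "shoot", "root")
    }
    if culture == "mix":
        ce = cfg.culture_effects[fertilization][genotype]
        means["leaf"] *= ce
        means["shoot"] *= ce
        shift = cfg.complementarity_shift.get(fertilization, {}).get(genotype, 0.0)
        if shift:
            agb = means["leaf"] + means["shoot"]
            per_plant = shift / (PLANTS_PER_POT // 2)
            means["leaf"] += per_plant * means["leaf"] / agb
            means["shoot"] += per_plant * means["shoot"] / agb
    return means


def _n_conc(cfg: GeneratorConfig, genotype: str, fertilization: str, organ: str, harvest: str) -> float:
    if harvest == "initial":
        return cfg.initial_n_conc[organ]
    c = cfg.baseline_n_conc[genotype][organ]
    if fertilization == "F+":
        c *= cfg.fertilization_conc_multiplier
    return c


def _initial_means(cfg: GeneratorConfig, genotype: str) -> dict:
    base = cfg.baseline_mass[genotype]
    return {organ: base[organ] * cfg.initial_fraction for organ in ("leaf", "shoot", "root")}


def expected_cells(cfg: GeneratorConfig) -> pd.DataFrame:
    """Closed-form expected per-plant values and derived traits per cell.

    One row per genotype x fertilization x culture combination of the final
    harvest; includes the expected organ masses, N pools, pot-level
    genotype yield and every trait the pipeline computes from them.
    """
    delta_t = (cfg.harvest_days[1] - cfg.harvest_days[0]) / 7.0
    rows = []
    for fert in ("F+", "F-"):
        for culture in ("mono", "mix"):
            for genotype in cfg.genotypes:
                means = _organ_means(cfg, genotype, fert, culture)
                init = _initial_means(cfg, genotype)
                n_plants = PLANTS_PER_POT if culture == "mono" else PLANTS_PER_POT // 2
                n_pools = {
                    organ: means[organ] * _n_conc(cfg, genotype, fert, organ, "final")
                    for organ in ("leaf", "shoot", "root")
                }
                n_init = {
                    organ: init[organ] * _n_conc(cfg, genotype, fert, organ, "initial")
                    for organ in ("leaf", "shoot", "root")
                }
                n_plant = sum(n_pools.values())
                n_plant_init = sum(n_init.values())
                n_s = cfg.cutting_mass[genotype] * cfg.cutting_n_conc[genotype]
                n_prime = (n_plant + n_plant_init) / 2.0
                m_total = sum(means.values())
                agb = means["leaf"] + means["shoot"]
                sla = cfg.sla_m2_per_kg[genotype]
                a_leaf = means["leaf"] * sla / 1000.0
                ln_la = n_pools["leaf"] / N_MOLAR_MASS * 1000.0 / a_leaf
                lnp = (means["leaf"] - init["leaf"]) / delta_t / float(
                    logarithmic_mean(n_init["leaf"] / N_MOLAR_MASS, n_pools["leaf"] / N_MOLAR_MASS)
                )
                dose = cfg.weekly_n_dose_mg[fert]
                n_fert_plant = dose * cfg.fertilization_weeks / 1000.0
                rows.append(
                    {
                        "genotype": genotype,
                        "fertilization": fert,
                        "culture": culture,
                        "n_plants": n_plants,
                        "m_leaf": means["leaf"],
                        "m_shoot": means["shoot"],
                        "m_root": means["root"],
                        "m_total": m_total,
                        "agb_per_plant": agb,
                        "pot_yield": agb * n_plants,
                        "a_leaf": a_leaf,
                        "N_leaf": n_pools["leaf"],
                        "N_plant": n_plant,
                        "N_plant_init": n_plant_init,
                        "SLA": sla,
                        "LAR": a_leaf / m_total,
                        "LMR": means["leaf"] / m_total,
                        "RMF": means["root"] / m_total,
                        "root_shoot": means["root"] / means["shoot"],
                        "SRL": cfg.srl_m_per_g,
                        "SRA": cfg.sra_cm2_per_g,
                        "RGR": np.log(means["leaf"] / init["leaf"]) / delta_t,
                        "LN/LA": ln_la,
                        "LNP": lnp,
                        "LAP": ln_la * 1e-3 * lnp,
                        "U_N": n_prime / n_s,
                        "E_N,y": means["shoot"] / n_prime,
                        "eta": (n_plant - n_plant_init) / n_fert_plant,
                    }
                )
    return pd.DataFrame(rows)


def truth_partition(cfg: GeneratorConfig) -> dict[str, PartitionResult]:
    """Expected diversity-effect partition per fertilization level.

    Computed analytically from the configured cell means: monoculture pot
    yield is six expected plants, each genotype's mixture yield is three
    expected mixture plants (including any additive shift).
    """
    cfg.validate()
    out = {}
    k = len(cfg.genotypes)
    p = 1.0 / k
    for fert in ("F+", "F-"):
        M = np.array(
            [sum(_organ_means(cfg, g, fert, "mono")[o] for o in ("leaf", "shoot")) * PLANTS_PER_POT
             for g in cfg.genotypes]
        )
        Y = np.array(
            [sum(_organ_means(cfg, g, fert, "mix")[o] for o in ("leaf", "shoot")) * (PLANTS_PER_POT // k)
             for g in cfg.genotypes]
        )
        dry = Y / M - p
        net = float(Y.sum() - p * M.sum())
        ce = float(k * dry.mean() * M.mean())
        se = float(((dry - dry.mean()) * (M - M.mean())).sum())
        out[fert] = PartitionResult(net=net, complementarity=ce, selection=se)
    return out


@dataclass
class SyntheticTruth:
    """Ground truth implied by a :class:`GeneratorConfig`, noise-free."""

    cells: pd.DataFrame
    partition: dict[str, PartitionResult]
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "partition": {f: p.as_dict() for f, p in self.partition.items()},
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            cells=pd.DataFrame(payload["cells"]),
            partition={f: PartitionResult(**p) for f, p in payload["partition"].items()},
            config=payload["config"],
        )


def build_truth(cfg: GeneratorConfig) -> SyntheticTruth:
    config_dict = dataclasses.asdict(cfg)
    config_dict["genotypes"] = list(cfg.genotypes)
    config_dict["harvest_days"] = list(cfg.harvest_days)
    return SyntheticTruth(cells=expected_cells(cfg), partition=truth_partition(cfg), config=config_dict)


class SyntheticExperiment(NamedTuple):
    plants: pd.DataFrame
    nitrogen: pd.DataFrame
    design: pd.DataFrame
    truth: SyntheticTruth


def _build_design(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    pot_no = 0
    for b in range(1, cfg.n_blocks + 1):
        for fert in ("F+", "F-"):
            for irr in ("W+", "W-"):
                for culture in ("mono", "mono", "mix"):
                    pot_no += 1
                    rows.append(
                        {
                            "block": f"B{b}",
                            "pot": f"P{pot_no:02d}",
                            "fertilization": fert,
                            "irrigation": irr,
                            "culture": culture,
                            "role": "factorial",
                        }
                    )
    # the two mono compositions per cell: tag after enumeration
    design = pd.DataFrame(rows)
    mono_genotype = []
    toggle: dict[tuple, int] = {}
    for _, row in design.iterrows():
        if row["culture"] == "mono":
            key = (row["block"], row["fertilization"], row["irrigation"])
            i = toggle.get(key, 0)
            mono_genotype.append(cfg.genotypes[i])
            toggle[key] = i + 1
        else:
            mono_genotype.append(None)
    design["mono_genotype"] = mono_genotype

    for genotype in cfg.genotypes:
        design = pd.concat(
            [
                design,
                pd.DataFrame(
                    [
                        {
                            "block": "B0",
                            "pot": f"I-{genotype}",
                            "fertilization": "F-",
                            "irrigation": "W+",
                            "culture": "mono",
                            "role": "initial",
                            "mono_genotype": genotype,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return design


def _mix_planting_order(genotypes: tuple[str, str]) -> list[str]:
    g1, g2 = genotypes
    # alternating rows: g1 g2 g1 / g2 g1 g2
    return [g1, g2, g1, g2, g1, g2]


def generate_experiment(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> SyntheticExperiment:
    """Generate one complete synthetic experiment.

    Returns plant, nitrogen and design tables in the documented CSV schemas
    plus the :class:`SyntheticTruth` implied by the configuration.  Output
    is byte-identical for identical ``config`` and ``seed`` (``seed``
    overrides ``config.seed`` when given).
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    design = _build_design(cfg)

    # enumerate plants in design order
    rows = []
    for _, pot_row in design.iterrows():
        harvest = "initial" if pot_row["role"] == "initial" else "final"
        if pot_row["culture"] == "mono":
            genotypes = [pot_row["mono_genotype"]] * PLANTS_PER_POT
        else:
            genotypes = _mix_planting_order(cfg.genotypes)
        for plant_no, genotype in enumerate(genotypes, start=1):
            rows.append(
                {
                    "pot": pot_row["pot"],
                    "plant": plant_no,
                    "genotype": genotype,
                    "harvest": harvest,
                    "fertilization": pot_row["fertilization"],
                    "culture": pot_row["culture"],
                }
            )
    plants = pd.DataFrame(rows)
    n = len(plants)

    means = np.empty((n, 3))
    for i, row in enumerate(plants.itertuples(index=False)):
        if row.harvest == "initial":
            m = _initial_means(cfg, row.genotype)
        else:
            m = _organ_means(cfg, row.genotype, row.fertilization, row.culture)
        means[i] = (m["leaf"], m["shoot"], m["root"])

    pot_codes, pot_index = pd.factorize(plants["pot"], sort=False)
    pot_effect = rng.normal(0.0, cfg.pot_sd, size=len(pot_index))
    plant_effect = rng.normal(0.0, cfg.sigma_plant, size=n)
    organ_effect = rng.normal(0.0, cfg.sigma_organ, size=(n, 3))
    correction = -(cfg.pot_sd**2 + cfg.sigma_plant**2 + cfg.sigma_organ**2) / 2.0
    log_factor = pot_effect[pot_codes][:, None] + plant_effect[:, None] + organ_effect + correction
    masses = means * np.exp(log_factor)

    cutting_base = plants["genotype"].map(cfg.cutting_mass).to_numpy()
    cutting_eps = rng.normal(0.0, cfg.cutting_sd, size=n)
    m_cutting = cutting_base * np.exp(cutting_eps - cfg.cutting_sd**2 / 2.0)

    sla = plants["genotype"].map(cfg.sla_m2_per_kg).to_numpy()
    plants["m_leaf"] = masses[:, 0]
    plants["m_shoot"] = masses[:, 1]
    plants["m_root"] = masses[:, 2]
    plants["m_cutting"] = m_cutting
    plants["a_leaf"] = masses[:, 0] * sla / 1000.0
    plants["n_leaves"] = np.maximum(1, np.round(masses[:, 0] * 15.0)).astype(int)
    plants["shoot_height"] = 0.25 * masses[:, 1] ** 0.4
    plants["shoot_diameter"] = 3.0 + 2.0 * np.sqrt(masses[:, 1])
    plants["l_root"] = masses[:, 2] * cfg.srl_m_per_g
    plants["a_root"] = masses[:, 2] * cfg.sra_cm2_per_g

    # pooled genotype-within-pot N measurements
    groups = (
        plants.groupby(["pot", "genotype", "harvest"], as_index=False, sort=True)
        .agg(
            m_leaf=("m_leaf", "sum"),
            m_shoot=("m_shoot", "sum"),
            m_root=("m_root", "sum"),
            m_cutting=("m_cutting", "sum"),
            fertilization=("fertilization", "first"),
        )
    )
    conc_eps = rng.normal(0.0, cfg.conc_sd, size=(len(groups), 4))
    conc_factor = np.exp(conc_eps - cfg.conc_sd**2 / 2.0)
    pools = np.empty((len(groups), 4))
    for i, row in enumerate(groups.itertuples(index=False)):
        concs = [
            _n_conc(cfg, row.genotype, row.fertilization, organ, row.harvest)
            for organ in ("leaf", "shoot", "root")
        ]
        pools[i, 0] = row.m_leaf * concs[0]
        pools[i, 1] = row.m_shoot * concs[1]
        pools[i, 2] = row.m_root * concs[2]
        pools[i, 3] = row.m_cutting * cfg.cutting_n_conc[row.genotype]
    pools *= conc_factor
    nitrogen = groups[["pot", "genotype", "harvest"]].copy()
    nitrogen["N_leaf"] = pools[:, 0]
    nitrogen["N_shoot"] = pools[:, 1]
    nitrogen["N_root"] = pools[:, 2]
    nitrogen["N_cutting"] = pools[:, 3]

    plants = plants.drop(columns=["fertilization", "culture"])
    design = design.drop(columns=["mono_genotype"])
    return SyntheticExperiment(plants=plants, nitrogen=nitrogen, design=design, truth=build_truth(cfg))


# ----------------------------------------------------------------------
# parameter-recovery harness


@dataclass
class RecoveryReport:
    """Distribution of estimated diversity effects across simulated datasets."""

    estimates: pd.DataFrame
    truth: dict[str, PartitionResult]
    n_datasets: int
    n_combinations: int
    alpha: float

    def summary(self) -> pd.DataFrame:
        """Per fertilization x effect: truth, mean/sd of estimates, bias,
        and the rate at which the resampling t-test rejected zero."""
        rows = []
        for fert, group in self.estimates.groupby("fertilization"):
            for effect in EFFECT_NAMES:
                true_value = getattr(self.truth[fert], effect)
                est = group[effect].to_numpy()
                rows.append(
                    {
                        "fertilization": fert,
                        "effect": effect,
                        "truth": true_value,
                        "mean": est.mean(),
                        "sd": est.std(ddof=1),
                        "bias": est.mean() - true_value,
                        "rejection_rate": float((group[f"p_{effect}"] < self.alpha).mean()),
                    }
                )
        return pd.DataFrame(rows)


def recovery_experiment(
    config: GeneratorConfig,
    n_datasets: int = 500,
    seed: int = 0,
    n_combinations: int = 300,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Simulate many experiments and re-estimate the diversity effects.

    Each dataset is generated with a fresh sub-seed, pooled through the
    standard pipeline path (irrigation demoted to replication), partitioned
    with ``n_combinations`` resampled pairings, and summarized.  The report
    compares the estimate distribution against :func:`truth_partition`.
    """
    config.validate()
    master = np.random.default_rng(seed)
    truth = truth_partition(config)
    rows = []
    for d in range(n_datasets):
        gen_seed = int(master.integers(2**31))
        resample_seed = int(master.integers(2**31))
        experiment = generate_experiment(config, seed=gen_seed)
        samples = pool_to_genotype_pot(
            experiment.plants, experiment.nitrogen, experiment.design, harvest_days=config.harvest_days
        )
        pooled = pool_irrigation_replicates(samples)
        _, summaries = partition_from_samples(pooled, n=n_combinations, seed=resample_seed)
        for fert, summary in summaries.items():
            row = {"dataset": d, "fertilization": fert}
            for effect in EFFECT_NAMES:
                row[effect] = summary.means[effect]
                row[f"p_{effect}"] = summary.p_values[effect]
            rows.append(row)
    return RecoveryReport(
        estimates=pd.DataFrame(rows),
        truth=truth,
        n_datasets=n_datasets,
        n_combinations=n_combinations,
        alpha=alpha,
    )
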