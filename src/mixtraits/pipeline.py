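"""End-to-end orchestration: load or simulate -> pool -> traits -> partition.

:func:`run_pipeline` drives the full chain and writes a reproducible
bundle of tidy outputs into the run directory:

``inputs/plants.csv``, ``inputs/nitrogen.csv``, ``inputs/design.csv``
    the (possibly simulated) raw tables actually analyzed;
``truth.json``
    generator ground truth (synthetic runs only);
``growth_traits.csv``, ``nitrogen_traits.csv``
    tidy long-format trait tables, one row per
    (block, pot, fertilization, irrigation, culture, genotype, trait);
``cell_summary.csv``
    mean +/- SE per trait x genotype x fertilization x culture cell;
``partition_combinations.csv``, ``partition_summary.csv``
    per-combination diversity-effect partitions and their resampling
    summary (mean, sd, t, p per effect and fertilization level);
``run_log.json``
    seed, resampling depth, analysis options and row counts.  The log
    contains no timestamps, so identical configurations reproduce
    byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import mixtraits
from mixtraits import experiment_model, synthetic_data
from mixtraits.diversity_effects import partition_from_samples
from mixtraits.growth_traits import compute_growth_traits
from mixtraits.nitrogen_economy import (
    DEFAULT_FERTILIZATION_WEEKS,
    DEFAULT_WEEKLY_DOSE_MG,
    compute_nitrogen_traits,
)

logger = logging.getLogger("mixtraits")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source must be set: either the three CSV paths
    (``plants``, ``nitrogen``, ``design``) or a synthetic
    :class:`~mixtraits.synthetic_data.GeneratorConfig` (``generator``).
    """

    outdir: str | Path = "mixtraits-run"
    plants: str | Path | None = None
    nitrogen: str | Path | None = None
    design: str | Path | None = None
    generator: synthetic_data.GeneratorConfig | None = None
    seed: int = 17
    n_combinations: int = 300
    rgr_basis: str = "leaf_mass"
    fertilization_weeks: int = DEFAULT_FERTILIZATION_WEEKS
    weekly_dose_mg: dict = field(default_factory=lambda: dict(DEFAULT_WEEKLY_DOSE_MG))
    pool_irrigation: bool = True

    def validate(self) -> None:
        paths = (self.plants, self.nitrogen, self.design)
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.generator is not None and some_paths:
            raise ValueError("set either CSV input paths or a generator config, not both")
        if self.generator is None and not has_paths:
            raise ValueError("input missing: provide plants/nitrogen/design paths or a generator config")
        if self.rgr_basis not in ("leaf_mass", "total_mass"):
            raise ValueError(f"rgr_basis must be 'leaf_mass' or 'total_mass', got {self.rgr_basis!r}")
        if self.n_combinations < 2:
            raise ValueError("n_combinations must be at least 2 for inference")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        generator = raw.pop("generator", None)
        config = cls(**raw)
        if generator is not None:
            config.generator = synthetic_data.GeneratorConfig(**generator)
        return config


@dataclass
class RunResult:
    outdir: Path
    growth_traits: pd.DataFrame
    nitrogen_traits: pd.DataFrame
    cell_summary: pd.DataFrame
    partition_combinations: pd.DataFrame
    partition_summary: pd.DataFrame
    files: dict[str, Path]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def summarize_by_cell(
    trait_table: pd.DataFrame,
    by: tuple[str, ...] = ("trait", "level", "genotype", "fertilization", "culture"),
) -> pd.DataFrame:
    """Cell means with standard errors for a tidy trait table.

    Returns one row per cell with ``mean``, ``sd``, ``se`` (= sd / sqrt(n))
    and ``n``; cells with a single observation get sd = se = NaN, empty
    cells do not appear (n would be 0).
    """
    keys = [c for c in by if c in trait_table.columns]
    grouped = trait_table.groupby(keys, as_index=False, dropna=False).agg(
        mean=("value", "mean"), sd=("value", "std"), n=("value", "size")
    )
    grouped["se"] = grouped["sd"] / grouped["n"].pow(0.5)
    return grouped


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis chain and write the output bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # --- acquire inputs -------------------------------------------------
    if config.generator is not None:
        experiment = _stage("simulate")(synthetic_data.generate_experiment, config.generator, config.seed)
        plants, nitrogen, design = experiment.plants, experiment.nitrogen, experiment.design
        truth_path = outdir / "truth.json"
        experiment.truth.to_json(truth_path)
        files["truth"] = truth_path
        harvest_days = config.generator.harvest_days
        logger.info("simulated experiment: %d plants, %d pots", len(plants), design.shape[0])
    else:
        plants = _stage("load")(experiment_model.read_plants, config.plants)
        nitrogen = _stage("load")(experiment_model.read_nitrogen, config.nitrogen)
        design = _stage("load")(experiment_model.read_design, config.design)
        harvest_days = experiment_model.DEFAULT_HARVEST_DAYS
    input_paths = _stage("write-inputs")(
        experiment_model.write_tables, plants, nitrogen, design, outdir / "inputs"
    )
    files.update({f"input_{k}": v for k, v in input_paths.items()})

    # --- pool -----------------------------------------------------------
    samples = _stage("pool")(
        experiment_model.pool_to_genotype_pot, plants, nitrogen, design, harvest_days
    )
    report = experiment_model.validate_design(samples)
    for violation in report.violations:
        logger.warning("design: %s", violation)
    if config.pool_irrigation:
        samples = _stage("pool")(experiment_model.pool_irrigation_replicates, samples)
    logger.info("pooled %d genotype-within-pot samples (%d pots)", len(samples), report.n_pots)

    # --- traits ----------------------------------------------------------
    growth = _stage("growth-traits")(compute_growth_traits, plants, samples, config.rgr_basis)
    nitro = _stage("nitrogen-traits")(
        compute_nitrogen_traits, samples, config.weekly_dose_mg, config.fertilization_weeks
    )
    traits = pd.concat([growth, nitro], ignore_index=True)
    cell_summary = _stage("summarize")(summarize_by_cell, traits)
    if (nitro.query("trait == 'eta'")["value"] > 1).any():
        logger.warning("eta > 1 observed: plant N gain exceeds fertilizer input for some groups")

    # --- diversity effects ----------------------------------------------
    combinations, summaries = _stage("partition")(
        partition_from_samples, samples, config.n_combinations, config.seed
    )
    summary_table = pd.concat(
        [s.table().assign(fertilization=fert) for fert, s in sorted(summaries.items())],
        ignore_index=True,
    )

    # --- write bundle -----------------------------------------------------
    outputs = {
        "growth_traits": growth,
        "nitrogen_traits": nitro,
        "cell_summary": cell_summary,
        "partition_combinations": combinations,
        "partition_summary": summary_table,
    }
    for name, frame in outputs.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        files[name] = path

    log = {
        "package_version": mixtraits.__version__,
        "seed": config.seed,
        "n_combinations": config.n_combinations,
        "rgr_basis": config.rgr_basis,
        "fertilization_weeks": config.fertilization_weeks,
        "weekly_dose_mg": config.weekly_dose_mg,
        "pool_irrigation": config.pool_irrigation,
        "input_source": "generator" if config.generator is not None else "csv",
        "row_counts": {name: int(len(frame)) for name, frame in outputs.items()},
        "design": {"n_pots": report.n_pots, "n_plants": report.n_plants, "violations": report.violations},
        "decisions": {
            "agb": "AGB = m_leaf + m_shoot; cutting and root excluded",
            "m_total": "m_total excludes the cutting (planting material)",
            "initial_values": "genotype-mean initial harvest broadcast to every final group",
            "eta_levels": "eta emitted per genotype share and per pot (community)",
            "resampling": "combinations drawn with replacement within fertilization level",
        },
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    files["run_log"] = log_path

    return RunResult(
        outdir=outdir,
        growth_traits=growth,
        nitrogen_traits=nitro,
        cell_summary=cell_summary,
        partition_combinations=combinations,
        partition_summary=summary_table,
        files=files,
    )
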