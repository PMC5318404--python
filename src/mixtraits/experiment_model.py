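"""Domain model, CSV input/output, design validation, and pooling.

The experimental unit hierarchy is::

    block > pot > genotype-within-pot > plant

Monoculture pots hold six plants of one genotype; mixture pots hold three
plants of each of the two genotypes (50:50 planting).  Organ dry masses and
leaf areas are recorded per plant; nitrogen pools are measured on material
pooled per genotype within each pot, so the genotype-within-pot group is the
finest level at which N-dependent quantities exist.

Three tidy CSV tables describe one experiment:

``design.csv``
    one row per pot: ``block, pot, fertilization, irrigation, culture, role``
    where ``role`` is ``factorial`` for the treatment design or ``initial``
    for the extra pots destructively harvested at the start of the
    fertilization period.
``plants.csv``
    one row per plant per harvest: ``pot, plant, genotype, harvest`` plus
    organ dry masses ``m_leaf, m_shoot, m_root, m_cutting`` (g), leaf area
    ``a_leaf`` (m^2), ``n_leaves`` (count), ``shoot_height`` (m),
    ``shoot_diameter`` (mm) and optional root morphology ``l_root`` (m),
    ``a_root`` (cm^2).
``nitrogen.csv``
    one row per genotype-within-pot group per harvest:
    ``pot, genotype, harvest`` plus N pools ``N_leaf, N_shoot, N_root,
    N_cutting`` (g N).

All masses are grams, areas m^2 (leaves) or cm^2 (roots), lengths m, time in
weeks since planting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FERTILIZATION_LEVELS = ("F+", "F-")
IRRIGATION_LEVELS = ("W+", "W-")
CULTURE_LEVELS = ("mono", "mix")
HARVEST_LEVELS = ("initial", "final")
ROLE_LEVELS = ("factorial", "initial")

#: Destructive harvests, in days after planting.
DEFAULT_HARVEST_DAYS = (34, 120)

#: Plants per pot (monoculture: all one genotype; mixture: split 3 + 3).
PLANTS_PER_POT = 6

DESIGN_COLUMNS = ["block", "pot", "fertilization", "irrigation", "culture", "role"]
PLANT_COLUMNS = [
    "pot",
    "plant",
    "genotype",
    "harvest",
    "m_leaf",
    "m_shoot",
    "m_root",
    "m_cutting",
    "a_leaf",
    "n_leaves",
    "shoot_height",
    "shoot_diameter",
    "l_root",
    "a_root",
]
NITROGEN_COLUMNS = ["pot", "genotype", "harvest", "N_leaf", "N_shoot", "N_root", "N_cutting"]

_MASS_COLUMNS = ["m_leaf", "m_shoot", "m_root", "m_cutting"]
_N_POOL_COLUMNS = ["N_leaf", "N_shoot", "N_root", "N_cutting"]


class SchemaError(ValueError):
    """A CSV does not carry the documented header."""


class ValidationError(ValueError):
    """A table violates a domain invariant (negative mass, orphan plant, ...)."""


class DomainError(ValueError):
    """A trait was requested outside its mathematical domain."""


@dataclass
class HarvestPair:
    """Initial- and final-harvest state of one genotype-within-pot group.

    ``initial`` and ``final`` are mappings (e.g. :class:`pandas.Series`)
    carrying the pooled group quantities; ``delta_t`` is the length of the
    main growth period in weeks.
    """

    initial: Mapping
    final: Mapping
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValidationError(f"delta_t must be positive, got {self.delta_t}")


@dataclass
class ValidationReport:
    """Findings from checking a loaded experiment against the factorial design."""

    n_pots: int
    n_plants: int
    composition: pd.DataFrame = field(repr=False)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"pots: {self.n_pots}", f"plants (final harvest): {self.n_plants}"]
        if self.violations:
            lines.append("violations:")
            lines.extend(f"  - {v}" for v in self.violations)
        else:
            lines.append("violations: none")
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {', '.join(missing)}")


def _check_nonnegative(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    for col in columns:
        bad = df.index[df[col].to_numpy() < 0]
        if len(bad):
            raise ValidationError(f"{name} row {bad[0]}: negative value in column '{col}'")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, dtype={"block": str, "pot": str})
    _require_columns(design, DESIGN_COLUMNS, "design table")
    for col, levels in (
        ("fertilization", FERTILIZATION_LEVELS),
        ("irrigation", IRRIGATION_LEVELS),
        ("culture", CULTURE_LEVELS),
        ("role", ROLE_LEVELS),
    ):
        bad = set(design[col]) - set(levels)
        if bad:
            raise ValidationError(f"design table: unknown {col} level(s) {sorted(bad)}")
    if design["pot"].duplicated().any():
        dup = design.loc[design["pot"].duplicated(), "pot"].iloc[0]
        raise ValidationError(f"design table: duplicated pot id '{dup}'")
    return design


def read_plants(path: str | Path) -> pd.DataFrame:
    plants = pd.read_csv(path, dtype={"pot": str, "genotype": str})
    _require_columns(plants, [c for c in PLANT_COLUMNS if c not in ("l_root", "a_root")], "plant table")
    for optional in ("l_root", "a_root"):
        if optional not in plants.columns:
            plants[optional] = np.nan
    bad_harvest = set(plants["harvest"]) - set(HARVEST_LEVELS)
    if bad_harvest:
        raise ValidationError(f"plant table: unknown harvest level(s) {sorted(bad_harvest)}")
    _check_nonnegative(plants, _MASS_COLUMNS + ["a_leaf"], "plant table")
    return plants


def read_nitrogen(path: str | Path) -> pd.DataFrame:
    nitrogen = pd.read_csv(path, dtype={"pot": str, "genotype": str})
    _require_columns(nitrogen, NITROGEN_COLUMNS, "nitrogen table")
    _check_nonnegative(nitrogen, _N_POOL_COLUMNS, "nitrogen table")
    return nitrogen


def load_tables(
    plant_csv: str | Path,
    nitrogen_csv: str | Path,
    design_csv: str | Path,
    harvest_days: tuple[int, int] = DEFAULT_HARVEST_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the three experiment CSVs and pool to genotype-within-pot samples.

    Returns ``(plants, samples)`` where ``plants`` is the validated
    plant-level table merged with the design factors and ``samples`` is the
    pooled genotype-within-pot table (see :func:`pool_to_genotype_pot`).
    """
    design = read_design(design_csv)
    plants = read_plants(plant_csv)
    nitrogen = read_nitrogen(nitrogen_csv)
    samples = pool_to_genotype_pot(plants, nitrogen, design, harvest_days=harvest_days)
    merged = plants.merge(design, on="pot", how="left", validate="many_to_one")
    if merged["block"].isna().any():
        orphan = merged.loc[merged["block"].isna(), "pot"].iloc[0]
        raise ValidationError(f"plant table: pot '{orphan}' has no design row")
    return merged, samples


def write_tables(
    plants: pd.DataFrame,
    nitrogen: pd.DataFrame,
    design: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three experiment tables as CSV; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plants": outdir / "plants.csv",
        "nitrogen": outdir / "nitrogen.csv",
        "design": outdir / "design.csv",
    }
    plants.to_csv(paths["plants"], index=False, columns=[c for c in PLANT_COLUMNS if c in plants.columns])
    nitrogen.to_csv(paths["nitrogen"], index=False, columns=NITROGEN_COLUMNS)
    design.to_csv(paths["design"], index=False, columns=DESIGN_COLUMNS)
    return paths


def pool_to_genotype_pot(
    plants: pd.DataFrame,
    nitrogen: pd.DataFrame,
    design: pd.DataFrame,
    harvest_days: tuple[int, int] = DEFAULT_HARVEST_DAYS,
) -> pd.DataFrame:
    """Pool plant records to the genotype-within-pot level and attach N pools.

    Masses, leaf areas and counts are summed within each
    ``(pot, genotype, harvest)`` group; per-plant means of the organ masses
    and leaf area are retained (``mean_`` columns) for individual-level
    traits.  Derived columns: ``m_total = m_leaf + m_shoot + m_root``
    (the cutting is planting material and is excluded), ``AGB = m_leaf +
    m_shoot``, ``N_plant = N_leaf + N_shoot + N_root``, and ``t_weeks`` =
    harvest day / 7.
    """
    _require_columns(plants, ["pot", "genotype", "harvest", "m_leaf", "m_shoot", "m_root"], "plant table")
    _require_columns(nitrogen, NITROGEN_COLUMNS, "nitrogen table")
    _require_columns(design, DESIGN_COLUMNS, "design table")

    unknown = set(plants["pot"]) - set(design["pot"])
    if unknown:
        raise ValidationError(
            f"plant table: pot(s) {sorted(unknown)} do not appear in the design table (orphan plants)"
        )

    summed = (
        plants.groupby(["pot", "genotype", "harvest"], as_index=False)
        .agg(
            n_plants=("plant", "size"),
            m_leaf=("m_leaf", "sum"),
            m_shoot=("m_shoot", "sum"),
            m_root=("m_root", "sum"),
            m_cutting=("m_cutting", "sum"),
            a_leaf=("a_leaf", "sum"),
            n_leaves=("n_leaves", "sum"),
            mean_m_leaf=("m_leaf", "mean"),
            mean_m_shoot=("m_shoot", "mean"),
            mean_m_root=("m_root", "mean"),
            mean_a_leaf=("a_leaf", "mean"),
        )
        .sort_values(["pot", "genotype", "harvest"], kind="stable")
        .reset_index(drop=True)
    )
    summed["m_total"] = summed["m_leaf"] + summed["m_shoot"] + summed["m_root"]
    summed["AGB"] = summed["m_leaf"] + summed["m_shoot"]

    samples = summed.merge(design, on="pot", how="left", validate="many_to_one")
    samples = samples.merge(
        nitrogen, on=["pot", "genotype", "harvest"], how="left", validate="one_to_one"
    )
    missing_n = samples["N_leaf"].isna()
    if missing_n.any():
        row = samples.loc[missing_n].iloc[0]
        raise ValidationError(
            f"nitrogen table: no N measurement for pot '{row['pot']}' genotype "
            f"'{row['genotype']}' harvest '{row['harvest']}'"
        )
    samples["N_plant"] = samples["N_leaf"] + samples["N_shoot"] + samples["N_root"]

    t_initial, t_final = (d / 7.0 for d in harvest_days)
    samples["t_weeks"] = np.where(samples["harvest"] == "initial", t_initial, t_final)

    ordered = [
        "block",
        "pot",
        "fertilization",
        "irrigation",
        "culture",
        "role",
        "genotype",
        "harvest",
        "t_weeks",
        "n_plants",
        "m_leaf",
        "m_shoot",
        "m_root",
        "m_cutting",
        "m_total",
        "AGB",
        "a_leaf",
        "n_leaves",
        "mean_m_leaf",
        "mean_m_shoot",
        "mean_m_root",
        "mean_a_leaf",
        "N_leaf",
        "N_shoot",
        "N_root",
        "N_cutting",
        "N_plant",
    ]
    return samples[ordered]


def validate_design(samples: pd.DataFrame) -> ValidationReport:
    """Check pooled samples against the full-factorial monoculture/mixture design.

    The canonical design is 2 fertilization x 2 irrigation x 3 pot
    compositions (two monocultures, one mixture) x ``n`` blocks, with six
    plants per pot.  Only pots with ``role == 'factorial'`` are checked; the
    initial-harvest pots sit outside the treatment design.
    """
    final = samples[(samples["role"] == "factorial") & (samples["harvest"] == "final")]
    violations: list[str] = []

    composition = final[["block", "pot", "fertilization", "irrigation", "culture", "genotype", "n_plants"]].copy()
    n_pots = final["pot"].nunique()
    n_plants = int(final["n_plants"].sum())

    for pot, group in final.groupby("pot"):
        culture = group["culture"].iloc[0]
        counts = dict(zip(group["genotype"], group["n_plants"]))
        if culture == "mono":
            if len(counts) != 1:
                violations.append(f"mono pot '{pot}' holds {len(counts)} genotypes: {sorted(counts)}")
            if sum(counts.values()) != PLANTS_PER_POT:
                violations.append(f"mono pot '{pot}' holds {sum(counts.values())} plants, expected {PLANTS_PER_POT}")
        else:
            if len(counts) != 2:
                violations.append(f"mix pot '{pot}' holds {len(counts)} genotypes: {sorted(counts)}")
            elif any(n != PLANTS_PER_POT // 2 for n in counts.values()):
                violations.append(
                    f"mix pot '{pot}' is not planted 50:50: " + ", ".join(f"{g}={n}" for g, n in sorted(counts.items()))
                )

    pots_per_block = final.groupby("block")["pot"].nunique()
    for block, count in pots_per_block.items():
        if count != 12:
            violations.append(f"block '{block}' has {count} pots, expected 12")

    # Every fertilization x irrigation x composition cell present in each block.
    genotypes = sorted(final["genotype"].unique())
    expected_compositions = [("mono", g) for g in genotypes] + [("mix", None)]
    for block, group in final.groupby("block"):
        for fert in FERTILIZATION_LEVELS:
            for irr in IRRIGATION_LEVELS:
                cell = group[(group["fertilization"] == fert) & (group["irrigation"] == irr)]
                for culture, genotype in expected_compositions:
                    if culture == "mono":
                        hit = cell[(cell["culture"] == "mono") & (cell["genotype"] == genotype)]
                    else:
                        hit = cell[cell["culture"] == "mix"]
                    if hit.empty:
                        label = f"mono({genotype})" if genotype else "mix"
                        violations.append(f"block '{block}': missing {fert}/{irr}/{label} pot")

    return ValidationReport(n_pots=n_pots, n_plants=n_plants, composition=composition, violations=violations)


def pool_irrigation_replicates(samples: pd.DataFrame) -> pd.DataFrame:
    """Demote the irrigation factor to a replicate label.

    When the irrigation contrast produces no treatment response it can be
    treated as extra replication, doubling the effective ``n`` per
    fertilization x culture x genotype cell.  The returned table has no
    ``irrigation`` column among its grouping keys; instead a ``replicate``
    label (block/irrigation) identifies the replicate pot.  A table without
    an irrigation column is passed through unchanged apart from the added
    ``replicate`` label.
    """
    pooled = samples.copy()
    if "irrigation" in pooled.columns:
        pooled["replicate"] = pooled["block"].astype(str) + "/" + pooled["irrigation"].astype(str)
        pooled = pooled.drop(columns=["irrigation"])
    elif "replicate" not in pooled.columns:
        pooled["replicate"] = pooled["block"].astype(str)
    return pooled


def broadcast_initial(samples: pd.DataFrame) -> pd.DataFrame:
    """Join genotype-mean initial-harvest state onto every final-harvest group.

    The initial harvest destroys only one pot per genotype, so initial
    values cannot be matched pot-by-pot.  Instead the per-plant genotype
    means from the initial harvest are broadcast to every final-harvest
    group of that genotype, scaled by the group's plant count so that both
    sides of each :class:`HarvestPair` are on the same (group) basis.

    Adds ``*_init`` columns for organ masses, leaf area and N pools plus
    ``t_init`` and ``delta_t`` (weeks).
    """
    initial = samples[samples["harvest"] == "initial"]
    final = samples[samples["harvest"] == "final"].copy()
    if initial.empty:
        raise ValidationError("no initial-harvest samples available to broadcast")

    per_plant = initial.set_index("genotype")
    quantities = ["m_leaf", "m_shoot", "m_root", "a_leaf", "N_leaf", "N_shoot", "N_root", "N_plant"]
    means = per_plant[quantities].div(per_plant["n_plants"], axis=0)
    means = means.groupby(level=0).mean()

    missing = set(final["genotype"]) - set(means.index)
    if missing:
        raise ValidationError(f"no initial-harvest data for genotype(s) {sorted(missing)}")

    t_init = float(initial["t_weeks"].iloc[0])
    for q in quantities:
        final[f"{q}_init"] = means.loc[final["genotype"], q].to_numpy() * final["n_plants"].to_numpy()
    final["t_init"] = t_init
    final["delta_t"] = final["t_weeks"] - t_init
    if (final["delta_t"] <= 0).any():
        raise ValidationError("final harvest must occur after the initial harvest")
    return final


def harvest_pairs(samples: pd.DataFrame) -> list[HarvestPair]:
    """Materialize :class:`HarvestPair` objects from a pooled sample table."""
    paired = broadcast_initial(samples)
    pairs = []
    for _, row in paired.iterrows():
        initial = {
            "m_leaf": row["m_leaf_init"],
            "m_shoot": row["m_shoot_init"],
            "m_root": row["m_root_init"],
            "a_leaf": row["a_leaf_init"],
            "N_leaf": row["N_leaf_init"],
            "N_shoot": row["N_shoot_init"],
            "N_root": row["N_root_init"],
            "N_plant": row["N_plant_init"],
            "t_weeks": row["t_init"],
        }
        pairs.append(HarvestPair(initial=initial, final=row, delta_t=float(row["delta_t"])))
    return pairs
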