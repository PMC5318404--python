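"""Nitrogen-economy indicator suite.

The indicators follow the two-harvest N budget methodology for woody
cuttings: the N content of the planted cutting is the perennial N store
``N_s``; the mean plant N during the main growth period is
``N' = (N_initial + N_harvest) / 2``; and the cumulative fertilizer input
closes the budget at pot level.

Indicators
----------
LNP
    leaf N productivity, g (mol N)^-1 wk^-1: biomass increment per week
    divided by the *logarithmic mean* of the leaf N pool (in mol) over the
    growth period.  The log mean is the exact time-average of an
    exponentially changing pool and degrades continuously to ``N_1`` when
    the pool does not change.
LAP
    leaf area productivity, g m^-2 wk^-1: (leaf N per area) x LNP.
U_N
    N uptake efficiency, g g^-1: ``N' / N_s``.
E_N,y
    yield-specific N efficiency, g g^-1: ``m_shoot / N'`` — harvestable
    shoot biomass per unit mean plant N.  By construction
    ``U_N x E_N,y = m_shoot / N_s`` exactly.
eta
    N retention efficiency, g g^-1: plant N gain over the period divided by
    the cumulative fertilizer N input.  Values above 1 indicate uptake from
    non-fertilizer sources (cutting reserves, substrate impurities) and are
    reported, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mixtraits.experiment_model import DomainError, broadcast_initial
from mixtraits.growth_traits import N_MOLAR_MASS, leaf_n_per_area

NITROGEN_TRAIT_UNITS = {
    "LNP": "g (mol N)-1 wk-1",
    "LAP": "g m-2 wk-1",
    "U_N": "g g-1",
    "E_N,y": "g g-1",
    "eta": "g g-1",
}

#: Default length of the weekly fertilization schedule (mid-June to
#: mid-September), weeks.
DEFAULT_FERTILIZATION_WEEKS = 13

#: Default weekly fertilizer dose per plant, mg N wk^-1, by treatment level.
DEFAULT_WEEKLY_DOSE_MG = {"F+": 8.4, "F-": 1.4}


@dataclass
class NitrogenBudget:
    """Per-group N bookkeeping over the main growth period (all in g N)."""

    n_initial: float
    n_harvest: float
    n_s: float
    n_fertilizer: float

    def __post_init__(self) -> None:
        for name in ("n_initial", "n_harvest", "n_s", "n_fertilizer"):
            if getattr(self, name) < 0:
                raise DomainError(f"NitrogenBudget.{name} must be non-negative")

    @property
    def n_prime(self) -> float:
        """Mean plant N during the main growth period."""
        return mean_plant_n(self.n_initial, self.n_harvest)


def mean_plant_n(n_initial, n_harvest):
    """Arithmetic mean of the plant N pool across the two harvests, g N."""
    return (np.asarray(n_initial, dtype=float) + np.asarray(n_harvest, dtype=float)) / 2.0


def logarithmic_mean(x1, x2):
    """Logarithmic mean ``(x2 - x1) / ln(x2/x1)`` with a continuous limit.

    Evaluated via a Taylor expansion when the ratio is within 1e-8 of 1, so
    the function is continuous (to better than 1e-9 relative) as x2 -> x1.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("logarithmic_mean requires positive arguments")
    r = b / a
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = a * (r - 1.0) / np.log(r)
    near = np.abs(r - 1.0) < 1e-8
    # log-mean ~ x1 * (1 + (r-1)/2) near r = 1
    taylor = a * (1.0 + (r - 1.0) / 2.0)
    return np.where(near, taylor, exact)


def leaf_n_productivity(n_leaf_initial, n_leaf_final, m_leaf_initial, m_leaf_final, delta_t):
    """Leaf N productivity, g (mol N)^-1 wk^-1.

    N pools are given in grams and converted to mol internally.  Equal to
    ``(dm/dt) / logmean(N_mol)``; when the leaf N pool is constant the
    log-mean factor reduces to ``1/N``.
    """
    n1, n2 = np.asarray(n_leaf_initial, float), np.asarray(n_leaf_final, float)
    m1, m2 = np.asarray(m_leaf_initial, float), np.asarray(m_leaf_final, float)
    dt = np.asarray(delta_t, float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise DomainError("leaf_n_productivity requires positive leaf N pools")
    if np.any(dt <= 0):
        raise DomainError("leaf_n_productivity requires delta_t > 0")
    n_mol_mean = logarithmic_mean(n1 / N_MOLAR_MASS, n2 / N_MOLAR_MASS)
    return (m2 - m1) / dt / n_mol_mean


def leaf_area_productivity(ln_la, lnp):
    """Leaf area productivity, g m^-2 wk^-1.

    ``ln_la`` is leaf N per area in mmol m^-2 and ``lnp`` leaf N
    productivity in g (mol N)^-1 wk^-1; the mmol -> mol factor 1e-3 is
    applied here.
    """
    return np.asarray(ln_la, float) * 1e-3 * np.asarray(lnp, float)


def n_uptake_efficiency(n_initial, n_harvest, n_s):
    """N uptake efficiency ``N' / N_s``, g g^-1."""
    ns = np.asarray(n_s, dtype=float)
    if np.any(ns <= 0):
        raise DomainError("n_uptake_efficiency requires cutting N (N_s) > 0")
    return mean_plant_n(n_initial, n_harvest) / ns


def yield_specific_n_efficiency(m_shoot, n_initial, n_harvest):
    """Yield-specific N efficiency ``m_shoot / N'``, g g^-1."""
    n_prime = mean_plant_n(n_initial, n_harvest)
    if np.any(np.asarray(n_prime) <= 0):
        raise DomainError("yield_specific_n_efficiency requires mean plant N (N') > 0")
    return np.asarray(m_shoot, dtype=float) / n_prime


def n_retention_efficiency(n_initial, n_harvest, n_fertilizer):
    """N retention efficiency ``(N_harvest - N_initial) / N_fertilizer``, g g^-1."""
    nf = np.asarray(n_fertilizer, dtype=float)
    if np.any(nf <= 0):
        raise DomainError("n_retention_efficiency requires fertilizer N input > 0")
    return (np.asarray(n_harvest, float) - np.asarray(n_initial, float)) / nf


def cumulative_fertilizer_n(weekly_dose_mg, n_plants=1, n_weeks=DEFAULT_FERTILIZATION_WEEKS):
    """Cumulative fertilizer N over the schedule, g N.

    ``weekly_dose_mg`` is the per-plant dose in mg N wk^-1; the pot (or
    genotype-share) input is the dose times the number of plants times the
    number of fertilization weeks.
    """
    dose = np.asarray(weekly_dose_mg, dtype=float)
    if np.any(dose <= 0):
        raise DomainError("cumulative_fertilizer_n requires a positive weekly dose")
    if n_weeks <= 0:
        raise DomainError("cumulative_fertilizer_n requires n_weeks > 0")
    return dose * np.asarray(n_plants, dtype=float) * n_weeks / 1000.0


def _tidy(keys: pd.DataFrame, trait: str, values, level: str) -> pd.DataFrame:
    out = keys.copy()
    out["trait"] = trait
    out["value"] = np.asarray(values, dtype=float)
    out["unit"] = NITROGEN_TRAIT_UNITS[trait]
    out["level"] = level
    return out


def compute_nitrogen_traits(
    samples: pd.DataFrame,
    weekly_dose_mg: dict[str, float] | None = None,
    fertilization_weeks: int = DEFAULT_FERTILIZATION_WEEKS,
) -> pd.DataFrame:
    """Evaluate the N-economy indicator suite over a pooled experiment table.

    All indicators except eta are computed per genotype-within-pot group
    (``level='genotype_pot'``), the level at which N was measured.  eta is
    emitted twice: per genotype share (fertilizer input split by planted
    proportion) and per pot (``level='community'``, genotype N gains summed
    against the whole-pot input).

    Returns a tidy table with the same schema as
    :func:`mixtraits.growth_traits.compute_growth_traits`.
    """
    doses = dict(DEFAULT_WEEKLY_DOSE_MG if weekly_dose_mg is None else weekly_dose_mg)

    paired = broadcast_initial(samples)
    paired = paired[paired["role"] == "factorial"].reset_index(drop=True)

    key_cols = ["block", "pot", "fertilization", "irrigation", "culture", "genotype"]
    key_cols = [c for c in key_cols if c in paired.columns]
    if "replicate" in paired.columns:
        key_cols.append("replicate")
    keys = paired[key_cols].reset_index(drop=True)

    dose = paired["fertilization"].map(doses)
    if dose.isna().any():
        level = paired.loc[dose.isna(), "fertilization"].iloc[0]
        raise DomainError(f"no weekly dose configured for fertilization level '{level}'")
    n_fert_group = cumulative_fertilizer_n(dose.to_numpy(), paired["n_plants"].to_numpy(), fertilization_weeks)

    lnp = leaf_n_productivity(
        paired["N_leaf_init"], paired["N_leaf"], paired["m_leaf_init"], paired["m_leaf"], paired["delta_t"]
    )
    ln_la = leaf_n_per_area(paired["N_leaf"], paired["a_leaf"])
    lap = leaf_area_productivity(ln_la, lnp)
    u_n = n_uptake_efficiency(paired["N_plant_init"], paired["N_plant"], paired["N_cutting"])
    e_ny = yield_specific_n_efficiency(paired["m_shoot"], paired["N_plant_init"], paired["N_plant"])
    eta_genotype = n_retention_efficiency(paired["N_plant_init"], paired["N_plant"], n_fert_group)

    pieces = [
        _tidy(keys, "LNP", lnp, "genotype_pot"),
        _tidy(keys, "LAP", lap, "genotype_pot"),
        _tidy(keys, "U_N", u_n, "genotype_pot"),
        _tidy(keys, "E_N,y", e_ny, "genotype_pot"),
        _tidy(keys, "eta", eta_genotype, "genotype_pot"),
    ]

    # community-level eta: whole-pot N gain over whole-pot fertilizer input
    pot = paired.copy()
    pot["n_gain"] = pot["N_plant"] - pot["N_plant_init"]
    pot["n_fert"] = n_fert_group
    group_cols = [c for c in key_cols if c not in ("genotype",)]
    # label the pot by its genotype composition so that summaries do not mix
    # the two monoculture types
    pot["composition"] = pot.groupby("pot")["genotype"].transform(lambda g: "+".join(sorted(set(g))))
    community = pot.groupby(group_cols + ["composition"], as_index=False).agg(
        n_gain=("n_gain", "sum"), n_fert=("n_fert", "sum")
    )
    comm_keys = community[group_cols + ["composition"]].rename(columns={"composition": "genotype"})
    comm_keys = comm_keys[[c for c in key_cols]]
    pieces.append(
        _tidy(
            comm_keys.reset_index(drop=True),
            "eta",
            (community["n_gain"] / community["n_fert"]).to_numpy(),
            "community",
        )
    )

    return pd.concat(pieces, ignore_index=True)
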