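"""Classical growth-analysis traits.

Scalar/array functions for the standard growth-analysis quantities —
relative growth rate (RGR), specific leaf area (SLA), leaf area ratio
(LAR), biomass allocation fractions (LMR, RMF, root:shoot), specific root
length/area (SRL, SRA) and leaf N per unit area (LN/LA) — plus
:func:`compute_growth_traits`, which evaluates them over a pooled
experiment table and emits a tidy long-format trait table.

Unit conventions: masses g, leaf area m^2, root length m, root area cm^2,
time weeks.  SLA is reported in m^2 kg^-1 (with the g -> kg factor
applied), LAR in m^2 g^-1, LN/LA in mmol N m^-2 using a molar mass of
14.0067 g mol^-1 for nitrogen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mixtraits.experiment_model import DomainError, broadcast_initial

#: Molar mass of nitrogen, g mol^-1.
N_MOLAR_MASS = 14.0067

#: Units of the emitted traits (tidy-table ``unit`` column).
TRAIT_UNITS = {
    "AGB": "g",
    "RGR": "g g-1 wk-1",
    "SLA": "m2 kg-1",
    "LAR": "m2 g-1",
    "LMR": "g g-1",
    "RMF": "g g-1",
    "root_shoot": "g g-1",
    "SRL": "m g-1",
    "SRA": "cm2 g-1",
    "LN/LA": "mmol N m-2",
}


def _as_arrays(*values):
    return [np.asarray(v, dtype=float) for v in values]


def relative_growth_rate(m_initial, m_final, delta_t):
    """Relative growth rate, g g^-1 wk^-1.

    ``(ln m_2 - ln m_1) / (t_2 - t_1)`` over the main growth period.  The
    mass basis (leaf mass or total mass) is whatever the caller passes in;
    the classical tabulation uses leaf mass.
    """
    m1, m2, dt = _as_arrays(m_initial, m_final, delta_t)
    if np.any(m1 <= 0) or np.any(m2 <= 0):
        raise DomainError("relative_growth_rate requires positive masses on both harvests")
    if np.any(dt <= 0):
        raise DomainError("relative_growth_rate requires delta_t > 0")
    return (np.log(m2) - np.log(m1)) / dt


def specific_leaf_area(a_leaf, m_leaf):
    """Specific leaf area, m^2 kg^-1 (leaf area per unit leaf dry mass)."""
    a, m = _as_arrays(a_leaf, m_leaf)
    if np.any(m <= 0):
        raise DomainError("specific_leaf_area requires m_leaf > 0")
    return a / m * 1000.0


def leaf_area_ratio(a_leaf, m_total):
    """Leaf area ratio, m^2 g^-1 (leaf area per unit total plant dry mass)."""
    a, m = _as_arrays(a_leaf, m_total)
    if np.any(m <= 0):
        raise DomainError("leaf_area_ratio requires m_total > 0")
    return a / m


def allocation_fractions(m_leaf, m_shoot, m_root):
    """Biomass allocation fractions.

    Returns a dict with ``LMR`` (leaf mass fraction of total), ``RMF``
    (root mass fraction) and ``root_shoot`` (root-to-shoot mass ratio).
    LMR + RMF + shoot fraction = 1 exactly; the cutting is excluded from
    the total throughout.
    """
    ml, ms, mr = _as_arrays(m_leaf, m_shoot, m_root)
    total = ml + ms + mr
    if np.any(total <= 0):
        raise DomainError("allocation_fractions requires m_total > 0")
    if np.any(ms <= 0):
        raise DomainError("allocation_fractions requires m_shoot > 0 for the root:shoot ratio")
    return {"LMR": ml / total, "RMF": mr / total, "root_shoot": mr / ms}


def root_morphology(l_root, a_root, m_root):
    """Specific root length (m g^-1) and specific root area (cm^2 g^-1).

    When morphology is measured on subsampled root fragments, pass the
    fragment totals; the ratios are unchanged as long as fragments are
    representative of the whole root system.
    """
    lr, ar, mr = _as_arrays(l_root, a_root, m_root)
    if np.any(mr <= 0):
        raise DomainError("root_morphology requires m_root > 0")
    return {"SRL": lr / mr, "SRA": ar / mr}


def leaf_n_per_area(n_leaf, a_leaf):
    """Leaf N content per unit leaf area, mmol N m^-2.

    ``n_leaf`` is the leaf N pool in grams; the conversion to mmol uses the
    molar mass 14.0067 g mol^-1.
    """
    n, a = _as_arrays(n_leaf, a_leaf)
    if np.any(a <= 0):
        raise DomainError("leaf_n_per_area requires a_leaf > 0")
    return n / N_MOLAR_MASS * 1000.0 / a


_KEY_COLUMNS = ["block", "pot", "fertilization", "irrigation", "culture", "genotype"]


def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in _KEY_COLUMNS if c in df.columns]
    if "replicate" in df.columns:
        keys.append("replicate")
    return df[keys].reset_index(drop=True)


def _tidy(keys: pd.DataFrame, trait: str, values, level: str) -> pd.DataFrame:
    out = keys.copy()
    out["trait"] = trait
    out["value"] = np.asarray(values, dtype=float)
    out["unit"] = TRAIT_UNITS[trait]
    out["level"] = level
    return out


def compute_growth_traits(
    plants: pd.DataFrame,
    samples: pd.DataFrame,
    rgr_basis: str = "leaf_mass",
) -> pd.DataFrame:
    """Evaluate the growth-analysis trait suite over an experiment.

    Per-plant traits (SLA, LAR, LMR, RMF, root:shoot, SRL, SRA) are computed
    for each final-harvest plant and then averaged within its
    genotype-within-pot group (``level='plant'``).  Group-level traits (AGB,
    RGR, LN/LA) use the pooled group sums, with the genotype-mean initial
    harvest broadcast to every final group for RGR (``level='genotype_pot'``).

    ``rgr_basis`` selects the RGR mass basis: ``'leaf_mass'`` (as in the
    classical tabulation) or ``'total_mass'``.

    Returns a tidy table with columns
    ``(block, pot, fertilization, irrigation, culture, genotype, trait,
    value, unit, level)``.
    """
    if rgr_basis not in ("leaf_mass", "total_mass"):
        raise ValueError(f"rgr_basis must be 'leaf_mass' or 'total_mass', got {rgr_basis!r}")

    paired = broadcast_initial(samples)
    paired = paired[paired["role"] == "factorial"].reset_index(drop=True)
    keys = _key_frame(paired)

    pieces: list[pd.DataFrame] = []

    # --- per-plant traits, averaged per genotype-within-pot group -------
    final_plants = plants[plants["harvest"] == "final"].copy()
    final_plants["SLA"] = specific_leaf_area(final_plants["a_leaf"], final_plants["m_leaf"])
    frac = allocation_fractions(final_plants["m_leaf"], final_plants["m_shoot"], final_plants["m_root"])
    final_plants["LMR"] = frac["LMR"]
    final_plants["RMF"] = frac["RMF"]
    final_plants["root_shoot"] = frac["root_shoot"]
    final_plants["LAR"] = leaf_area_ratio(
        final_plants["a_leaf"],
        final_plants["m_leaf"] + final_plants["m_shoot"] + final_plants["m_root"],
    )
    measured = final_plants["m_root"] > 0
    morph_ok = measured & final_plants["l_root"].notna() & final_plants["a_root"].notna()
    final_plants.loc[morph_ok, "SRL"] = (
        final_plants.loc[morph_ok, "l_root"] / final_plants.loc[morph_ok, "m_root"]
    )
    final_plants.loc[morph_ok, "SRA"] = (
        final_plants.loc[morph_ok, "a_root"] / final_plants.loc[morph_ok, "m_root"]
    )

    plant_means = (
        final_plants.groupby(["pot", "genotype"], as_index=False)[
            ["SLA", "LMR", "RMF", "root_shoot", "LAR", "SRL", "SRA"]
        ].mean()
    )
    merged = paired.merge(plant_means, on=["pot", "genotype"], how="left", validate="one_to_one")
    for trait in ("SLA", "LAR", "LMR", "RMF", "root_shoot", "SRL", "SRA"):
        values = merged[trait]
        if values.notna().any():
            mask = values.notna().to_numpy()
            pieces.append(_tidy(keys[mask], trait, values[mask], "plant"))

    # --- group-level traits ---------------------------------------------
    pieces.append(_tidy(keys, "AGB", paired["AGB"], "genotype_pot"))
    if rgr_basis == "leaf_mass":
        rgr = relative_growth_rate(paired["m_leaf_init"], paired["m_leaf"], paired["delta_t"])
    else:
        total_init = paired["m_leaf_init"] + paired["m_shoot_init"] + paired["m_root_init"]
        rgr = relative_growth_rate(total_init, paired["m_total"], paired["delta_t"])
    pieces.append(_tidy(keys, "RGR", rgr, "genotype_pot"))
    pieces.append(_tidy(keys, "LN/LA", leaf_n_per_area(paired["N_leaf"], paired["a_leaf"]), "genotype_pot"))

    return pd.concat(pieces, ignore_index=True)
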