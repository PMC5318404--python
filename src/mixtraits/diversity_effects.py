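"""Additive partitioning of diversity effects and replicate-pairing inference.

For a mixture of ``k`` genotypes with monoculture yields ``M_i`` and
observed per-genotype mixture yields ``Y_Oi`` (both g aboveground biomass
per pot), with planted proportions ``p_i``:

.. math::

    RY_{Oi} = Y_{Oi} / M_i, \\qquad \\Delta RY_i = RY_{Oi} - p_i

    \\text{net} = \\sum_i Y_{Oi} - \\sum_i p_i M_i
    = \\underbrace{k\\,\\overline{\\Delta RY}\\,\\overline{M}}_{\\text{complementarity}}
    + \\underbrace{k\\,\\mathrm{cov}(\\Delta RY, M)}_{\\text{selection}}

where the covariance is the population (1/k) covariance, so the selection
effect equals the term-by-term sum
``sum_i (dRY_i - mean dRY)(M_i - mean M)``.  The identity
net = complementarity + selection holds to machine precision.

A positive selection effect means the genotype that performs best in
monoculture dominates the mixture; a positive complementarity effect means
the genotypes jointly overyield relative to their monocultures.

Because replicate pots are not naturally paired, monoculture/mixture
combinations are formed by resampling: each combination draws one
monoculture pot per genotype and one mixture pot uniformly at random (with
replacement) within a fertilization level.  Effects are then averaged over
combinations and tested against zero with a two-tailed one-sample
Student t-test.  Note that combinations re-use the same replicate pots, so
the combination-level t-test treats resampling draws, not independent
experimental units, as replicates; the per-combination table is exported so
that alternative inference can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mixtraits.experiment_model import DomainError


@dataclass
class PartitionResult:
    """Additive partition of the net diversity effect (g per pot)."""

    net: float
    complementarity: float
    selection: float

    def as_dict(self) -> dict[str, float]:
        return {"net": self.net, "complementarity": self.complementarity, "selection": self.selection}


@dataclass
class MonoMixCombination:
    """One monoculture/mixture pairing entering the partition."""

    genotypes: tuple[str, ...]
    mono_yields: np.ndarray
    mix_yields: np.ndarray
    proportions: np.ndarray | None = None
    fertilization: str | None = None
    mono_pots: tuple[str, ...] | None = None
    mix_pot: str | None = None

    def __post_init__(self) -> None:
        self.mono_yields = np.asarray(self.mono_yields, dtype=float)
        self.mix_yields = np.asarray(self.mix_yields, dtype=float)
        k = len(self.genotypes)
        if self.proportions is None:
            self.proportions = np.full(k, 1.0 / k)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not (len(self.mono_yields) == len(self.mix_yields) == len(self.proportions) == k):
            raise ValueError("genotypes, yields and proportions must have equal length")
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("planted proportions must sum to 1")
        if np.any(self.mono_yields <= 0):
            raise DomainError("monoculture yields must be positive")


def partition_many(mono_yields, mix_yields, proportions=None):
    """Vectorized additive partition.

    ``mono_yields`` and ``mix_yields`` are arrays of shape ``(..., k)``;
    returns ``(net, complementarity, selection)`` arrays of shape ``(...)``.
    """
    M = np.asarray(mono_yields, dtype=float)
    Y = np.asarray(mix_yields, dtype=float)
    if M.shape != Y.shape:
        raise ValueError("mono_yields and mix_yields must have the same shape")
    if np.any(M <= 0):
        raise DomainError("monoculture yields must be positive")
    k = M.shape[-1]
    p = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions, dtype=float)
    dry = Y / M - p
    net = Y.sum(axis=-1) - (p * M).sum(axis=-1)
    complementarity = k * dry.mean(axis=-1) * M.mean(axis=-1)
    selection = (
        (dry - dry.mean(axis=-1, keepdims=True)) * (M - M.mean(axis=-1, keepdims=True))
    ).sum(axis=-1)
    return net, complementarity, selection


def partition_additive(combination: MonoMixCombination) -> PartitionResult:
    """Additively partition one combination into net = complementarity + selection."""
    net, ce, se = partition_many(
        combination.mono_yields[None, :],
        combination.mix_yields[None, :],
        combination.proportions,
    )
    return PartitionResult(net=float(net[0]), complementarity=float(ce[0]), selection=float(se[0]))


def sample_combinations(
    mono_pots: Mapping[str, Sequence[float]],
    mix_pots: Mapping[str, Sequence[float]],
    n: int = 300,
    seed: int | np.random.Generator | None = None,
    proportions=None,
    fertilization: str | None = None,
    mono_pot_ids: Mapping[str, Sequence[str]] | None = None,
    mix_pot_ids: Sequence[str] | None = None,
) -> list[MonoMixCombination]:
    """Draw ``n`` random monoculture/mixture combinations.

    ``mono_pots`` maps each genotype to its replicate monoculture pot yields
    (g AGB per pot); ``mix_pots`` maps each genotype to its per-genotype
    yields observed in the replicate mixture pots, aligned so that index
    ``j`` refers to the same mixture pot for every genotype.  Each
    combination draws, uniformly at random with replacement, one
    monoculture pot per genotype and one mixture pot.  Sampling is fully
    reproducible for a fixed ``seed``.
    """
    genotypes = tuple(mono_pots)
    if tuple(mix_pots) != genotypes:
        raise ValueError("mono_pots and mix_pots must list the same genotypes in the same order")
    mono = {g: np.asarray(v, dtype=float) for g, v in mono_pots.items()}
    mix = np.column_stack([np.asarray(mix_pots[g], dtype=float) for g in genotypes])
    for g, v in mono.items():
        if v.size == 0:
            raise ValueError(f"no monoculture replicate pots for genotype '{g}'")
    if mix.shape[0] == 0:
        raise ValueError("no mixture replicate pots")
    if n < 1:
        raise ValueError("n must be at least 1")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mono_idx = {g: rng.integers(0, mono[g].size, size=n) for g in genotypes}
    mix_idx = rng.integers(0, mix.shape[0], size=n)

    combos = []
    for i in range(n):
        mono_ids = (
            tuple(str(mono_pot_ids[g][mono_idx[g][i]]) for g in genotypes) if mono_pot_ids else None
        )
        combos.append(
            MonoMixCombination(
                genotypes=genotypes,
                mono_yields=np.array([mono[g][mono_idx[g][i]] for g in genotypes]),
                mix_yields=mix[mix_idx[i]],
                proportions=proportions,
                fertilization=fertilization,
                mono_pots=mono_ids,
                mix_pot=str(mix_pot_ids[mix_idx[i]]) if mix_pot_ids is not None else None,
            )
        )
    return combos


@dataclass
class ResamplingSummary:
    """Resampled diversity effects with one-sample t inference.

    ``means``/``sds`` are per-effect statistics over the combinations; the
    t statistic is ``mean / (sd / sqrt(n))`` with ``n - 1`` degrees of
    freedom and a two-tailed p-value.  A zero-variance set of effects is
    flagged ``degenerate`` and its p-value reported as the limit 0 (or 1
    when the mean is also zero).
    """

    n_combinations: int
    effects: pd.DataFrame = field(repr=False)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    t_statistics: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)
    seed: int | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for effect in self.means:
            rows.append(
                {
                    "effect": effect,
                    "mean": self.means[effect],
                    "sd": self.sds[effect],
                    "t": self.t_statistics[effect],
                    "p": self.p_values[effect],
                    "n": self.n_combinations,
                    "degenerate": self.degenerate[effect],
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


EFFECT_NAMES = ("net", "complementarity", "selection")


def summarize_effects(partitions, seed: int | None = None) -> ResamplingSummary:
    """Mean, sd and one-sample t-test per effect over a set of partitions.

    ``partitions`` is a sequence of :class:`PartitionResult` or a DataFrame
    with columns ``net, complementarity, selection``.
    """
    if isinstance(partitions, pd.DataFrame):
        effects = partitions[list(EFFECT_NAMES)].reset_index(drop=True)
    else:
        effects = pd.DataFrame([p.as_dict() for p in partitions])
    n = len(effects)
    if n < 2:
        raise ValueError("at least two partitions are required for inference")

    means, sds, ts, ps, degenerate = {}, {}, {}, {}, {}
    for effect in EFFECT_NAMES:
        x = effects[effect].to_numpy()
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        means[effect], sds[effect] = mean, sd
        if sd == 0.0:
            degenerate[effect] = True
            if mean == 0.0:
                ts[effect], ps[effect] = 0.0, 1.0
            else:
                ts[effect] = float(np.inf if mean > 0 else -np.inf)
                ps[effect] = 0.0
        else:
            degenerate[effect] = False
            t = mean / (sd / np.sqrt(n))
            ts[effect] = float(t)
            ps[effect] = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return ResamplingSummary(
        n_combinations=n,
        effects=effects,
        means=means,
        sds=sds,
        t_statistics=ts,
        p_values=ps,
        degenerate=degenerate,
        seed=seed,
    )


def resample_partition(
    mono_pots: Mapping[str, Sequence[float]],
    mix_pots: Mapping[str, Sequence[float]],
    n: int = 300,
    seed: int | np.random.Generator | None = None,
    fertilization: str | None = None,
    mono_pot_ids: Mapping[str, Sequence[str]] | None = None,
    mix_pot_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, ResamplingSummary]:
    """Sample combinations, partition each, and summarize.

    Returns ``(combinations, summary)`` where ``combinations`` is a tidy
    per-combination table (one row per resampled pairing with its yields,
    pot ids when given, and partition terms).
    """
    combos = sample_combinations(
        mono_pots,
        mix_pots,
        n=n,
        seed=seed,
        fertilization=fertilization,
        mono_pot_ids=mono_pot_ids,
        mix_pot_ids=mix_pot_ids,
    )
    genotypes = combos[0].genotypes
    M = np.stack([c.mono_yields for c in combos])
    Y = np.stack([c.mix_yields for c in combos])
    net, ce, se = partition_many(M, Y, combos[0].proportions)

    table = pd.DataFrame({"combination": np.arange(len(combos))})
    if fertilization is not None:
        table["fertilization"] = fertilization
    for j, g in enumerate(genotypes):
        table[f"M_{g}"] = M[:, j]
        table[f"Y_{g}"] = Y[:, j]
        if combos[0].mono_pots is not None:
            table[f"mono_pot_{g}"] = [c.mono_pots[j] for c in combos]
    if combos[0].mix_pot is not None:
        table["mix_pot"] = [c.mix_pot for c in combos]
    table["net"] = net
    table["complementarity"] = ce
    table["selection"] = se

    summary = summarize_effects(table, seed=seed if isinstance(seed, int) else None)
    return table, summary


def extract_agb_pots(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-pot per-genotype aboveground biomass from a pooled sample table.

    Keeps final-harvest factorial pots only; returns columns
    ``(pot, genotype, fertilization, culture, AGB)`` plus ``block`` when
    present.
    """
    final = samples[(samples["harvest"] == "final") & (samples.get("role", "factorial") == "factorial")]
    cols = [c for c in ("block", "pot", "fertilization", "culture", "genotype", "AGB") if c in final.columns]
    return final[cols].reset_index(drop=True)


def partition_from_samples(
    samples: pd.DataFrame,
    n: int = 300,
    seed: int | None = None,
    genotypes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, ResamplingSummary]]:
    """Resampled additive partitioning within each fertilization level.

    ``samples`` is a pooled (genotype-within-pot) table; pot-level AGB is
    extracted, monoculture and mixture replicate pots are identified, and
    :func:`resample_partition` is run separately per fertilization level
    with a sub-seed derived deterministically from ``seed``.

    Returns the concatenated per-combination table and a summary per
    fertilization level.
    """
    agb = extract_agb_pots(samples)
    if genotypes is None:
        genotypes = sorted(agb["genotype"].unique())
    rng = np.random.default_rng(seed)

    tables = []
    summaries: dict[str, ResamplingSummary] = {}
    for fert in sorted(agb["fertilization"].unique()):
        cell = agb[agb["fertilization"] == fert]
        mono = cell[cell["culture"] == "mono"]
        mix = cell[cell["culture"] == "mix"]
        mono_pots = {}
        mono_ids = {}
        for g in genotypes:
            sub = mono[mono["genotype"] == g]
            mono_pots[g] = sub["AGB"].to_numpy()
            mono_ids[g] = sub["pot"].to_list()
        mix_wide = mix.pivot(index="pot", columns="genotype", values="AGB")
        if mix_wide.isna().any().any():
            raise DomainError("every mixture pot must report AGB for both genotypes")
        mix_pots = {g: mix_wide[g].to_numpy() for g in genotypes}
        table, summary = resample_partition(
            mono_pots,
            mix_pots,
            n=n,
            seed=rng,
            fertilization=fert,
            mono_pot_ids=mono_ids,
            mix_pot_ids=mix_wide.index.to_list(),
        )
        if seed is not None:
            summary.seed = seed
        tables.append(table)
        summaries[fert] = summary
    return pd.concat(tables, ignore_index=True), summaries


@dataclass
class RobustnessReport:
    """Significance verdicts for different resampling depths."""

    table: pd.DataFrame
    consistent: bool


def iteration_robustness(
    mono_pots: Mapping[str, Sequence[float]],
    mix_pots: Mapping[str, Sequence[float]],
    seed: int | None = None,
    n_values: Sequence[int] = (10, 50, 300),
    alpha: float = 0.05,
) -> RobustnessReport:
    """Check that significance verdicts agree across resampling depths.

    Because the number of resampled combinations is arbitrary, a robust
    effect should yield the same verdict whether 10, 50 or 300 combinations
    are drawn.  Runs :func:`resample_partition` once per ``n`` (with
    sub-seeds derived from ``seed``) and flags any verdict disagreement.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        _, summary = resample_partition(mono_pots, mix_pots, n=n, seed=rng)
        for effect in EFFECT_NAMES:
            rows.append(
                {
                    "n": n,
                    "effect": effect,
                    "mean": summary.means[effect],
                    "p": summary.p_values[effect],
                    "significant": summary.p_values[effect] < alpha,
                }
            )
    table = pd.DataFrame(rows)
    consistent = bool((table.groupby("effect")["significant"].nunique() == 1).all())
    return RobustnessReport(table=table, consistent=consistent)
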