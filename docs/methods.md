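# Methods

This note documents the models, conventions and design choices behind
`mixtraits`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Experimental model

The unit hierarchy is block > pot > genotype-within-pot > plant. Organ dry
masses (leaf, shoot, root, cutting), leaf area and shoot dimensions are
plant-level measurements; N pools are measured on material pooled per
genotype within each pot, so the genotype-within-pot group is the finest
level carrying N. Monoculture pots hold six plants of one genotype,
mixture pots three of each (planted 50:50). The canonical factorial is
2 fertilization (F+/F−) × 2 irrigation (W+/W−) × {two monocultures, one
mixture} × 4 blocks = 48 pots, 288 plants, plus one extra pot per genotype
harvested at the start of the fertilization period ("initial" harvest,
day 34; final harvest day 120; Δt = 86/7 ≈ 12.29 weeks).

Conventions, fixed once and used everywhere:

- **AGB = m_leaf + m_shoot** and **m_total = m_leaf + m_shoot + m_root**.
  The cutting is planting material, not biomass produced by the
  experiment, and is excluded from both.
- **Time** is in weeks since planting (harvest day / 7).
- **Units**: masses g, leaf area m², root length m, root area cm², N pools
  g N; molar conversions use 14.0067 g mol⁻¹. SLA is reported in
  m² kg⁻¹, LAR in m² g⁻¹, LN/LA in mmol N m⁻².
- **Initial-harvest broadcast**: only one pot per genotype exists at the
  initial harvest, so per-plant genotype means from that harvest are
  broadcast to every final-harvest group of the genotype, scaled by the
  group's plant count. All two-harvest quantities (RGR, LNP, U_N, η) are
  ratios or scale with group size consistently, so this choice does not
  introduce a mono/mix size artifact.
- **Irrigation as replication**: when the irrigation contrast produces no
  response it is demoted to a replicate label, doubling n per
  fertilization × culture × genotype cell (4 → 8 pots).

## Trait definitions

Per-plant traits (SLA, LAR, LMR, RMF, root:shoot, SRL, SRA) are computed
per plant and averaged within the genotype-within-pot group. N-dependent
and two-harvest traits are computed at the group level, where N exists:

- RGR = (ln m₂ − ln m₁)/Δt, by default on leaf mass as in the classical
  two-harvest tabulation; a whole-plant basis (`rgr_basis="total_mass"`)
  is exposed because classical growth analysis more commonly uses total
  mass. Neither is presumed "correct"; the default follows the printed
  definition.
- LNP = (Δm_leaf/Δt) / N̄_log with N̄_log the logarithmic mean of the leaf
  N pool in mol. The log mean is the exact time average of an
  exponentially changing pool; it is evaluated with a second-order Taylor
  expansion when N₂/N₁ is within 10⁻⁸ of 1, making it continuous to better
  than 10⁻⁹ relative at N₂ → N₁ (limit 1/N₁ for the reciprocal factor).
- U_N = N′/N_s and E_N,y = m_shoot/N′ with N′ = (N_initial +
  N_harvest)/2 and N_s the cutting N. The printed expression for E_N,y is
  ambiguous about operator precedence; the g g⁻¹ unit and the N′
  definition force the reading m_shoot / [(N_initial + N_harvest)/2].
  With both defined through the same N′, U_N × E_N,y = m_shoot/N_s is an
  exact identity and is enforced by test.
- η = (N_harvest − N_initial)/N_fertilizer. Values above 1 are possible
  (uptake from cutting reserves or substrate) and are reported with a
  warning, not clipped.

## Fertilizer accounting

The weekly doses (1.4 mg N wk⁻¹ at F−, 8.4 at F+ — the 20 vs 120
kg N ha⁻¹ yr⁻¹ contrast) are interpreted **per plant**. A per-pot reading
is inconsistent with the reported η range: six plants at any realistic
tissue N concentration would gain several times a per-pot input, forcing
η ≫ 1. Cumulative input is dose × plants × fertilization weeks
(default 13, the mid-June to mid-September schedule). In mixture pots the
input is split 50:50 by planted proportion for genotype-level budgets;
community-level η uses the whole pot. Both aggregations are emitted, since
it is not generally determinable which one a given report used.

## Additive partition and resampling inference

The net diversity effect is partitioned exactly as
net = k·mean(ΔRY)·mean(M) + k·cov(ΔRY, M), with the population (1/k)
covariance, so for two genotypes the selection term equals the
term-by-term sum Σ(ΔRY_i − mean)(M_i − mean). Expected relative yields are
the planted proportions (0.5/0.5). Additivity holds to machine precision
and is checked against an independent brute-force evaluation.

Replicate pots are unpaired, so combinations are resampled: each draws one
monoculture pot per genotype and one mixture pot uniformly **with
replacement** within a fertilization level (with replacement makes an
arbitrary number of combinations, e.g. 300, well defined for 7–8
replicates). Sampling is seedable and byte-reproducible; pot identities
are exported per combination.

**Calibration caveat.** The one-sample t-test on the n resampled
combination effects (t = mean/(sd/√n), df = n − 1) treats resampling draws
as replicates. But the combinations re-use the same 7–8 pots: as n grows,
the mean effect converges to the dataset's fixed finite-replicate value
while the denominator shrinks like 1/√n, so t measures Monte-Carlo error,
not experimental error. Under the package's own null generator the test
rejects far above the nominal level (the acceptance suite measures this),
and the excess depends only on the replicate counts, not the noise
magnitude — which also explains why 10, 50 and 300 combinations give the
same verdicts (a property the suite does verify). Aggregating to mixture-
pot level before testing was evaluated and is still anticonservative
(all units share the monoculture pot means). The per-combination table is
exported precisely so that users can apply inference appropriate to their
replication structure; the combination-level t-test is retained as the
field's customary summary, not as a calibrated error rate.

## Synthetic-data generator

The generator reproduces the statistical structure of the experiment, not
its mechanism (no light competition or soil N dynamics):

- **Cell means.** Per-genotype baseline organ masses at F−/monoculture,
  multiplied by per-organ fertilization effects (default 2.5 aboveground,
  1.6 root — allocation shifts belowground at low N), per-fertilization ×
  per-genotype multiplicative mixture effects on the aboveground organs,
  and optionally an additive per-genotype mixture yield shift. Organ N =
  mass × concentration, with per-genotype concentrations raised 1.5× at
  F+. Defaults encode one genotype ('Loden') as the larger monoculture
  with lower tissue N, the other ('Tora') as smaller but N-acquisitive,
  overyielding in mixture at F−, both underyielding at F+ — producing
  positive complementarity with negative selection at F− and strongly
  negative complementarity at F+, and community η higher at F− than F+.
- **Noise.** Lognormal, mean-corrected on the log scale: plant-size factor
  (σ = 0.30), organ-level jitter (σ = 0.10), pot random effect
  (σ = 0.10), genotype-pot N-concentration jitter (σ = 0.05), cutting mass
  jitter (σ = 0.08). Sizes are positive and right-skewed; the mean
  correction (−σ²/2 per component) makes expectations equal the configured
  cell means exactly, so the σ = 0 limit reproduces the closed-form truth
  to 10⁻⁹ relative through the whole pipeline (tested). The pot-effect and
  noise magnitudes are order-of-magnitude choices — they are not
  recoverable from published summaries — and should be re-examined before
  using the generator to power a real design.
- **Irrigation** is generated as a pure replicate label with no effect
  (mirroring an irrigation contrast that induced no water stress).
- **Initial harvest**: plants at the 1–2 leaf stage, masses a configurable
  fraction (default 0.03) of the F− baseline with young-tissue N
  concentrations.
- **Truth.** `expected_cells` evaluates every trait analytically from the
  configuration; `truth_partition` gives the implied diversity-effect
  partition per fertilization level. `GeneratorConfig.null()` (no mixture
  response) and `GeneratorConfig.complementarity_only()` (exchangeable
  genotypes with a shared overyield, so selection is exactly zero) are the
  canned conditions used by the recovery and calibration simulations.

What passing tests on synthetic data do **not** show: the generator has no
genotype × block interaction, no spatial structure, no measurement error
distinct from biological variation, and mixture effects enter as constant
multipliers — real mixture responses may be density- or size-dependent.
Recovery results therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to field realities.

## Estimator bias at finite replication

Relative yields divide by a noisy monoculture yield, so
E[Y/M] = (E[Y]/E[M])(1 + CV²_M + …). This inflates the complementarity
estimate and deflates selection by ≈ E[Y]·CV²_M (a few percent of the
effect at the default noise levels); the net effect is unbiased. The
recovery simulation quantifies this: the acceptance suite requires the
mean complementarity estimate within 10% of truth and the selection
estimate centered within 5% of the injected effect over 500 datasets.

## Problem sizes

Monte-Carlo checks use 500 simulated datasets (recovery, null
calibration), 10,000 random combinations (additivity/oracle equivalence),
and 300 resampled combinations per partition — sizes at which each check
runs in well under a minute on one core while leaving Monte-Carlo standard
errors small relative to the tolerances tested.

## Known limitations

- Two genotypes only; the tripartite (dominance/trait-dependent) partition
  is out of scope.
- The combination-level t-test is not a calibrated error rate (see above).
- Exactly two harvests; no growth-curve smoothing.
- Root morphology is taken from (sub)sampled fragments as given; no image
  analysis.
- Linear mixed models, ANOVA/ANCOVA and post-hoc tests are deliberately
  not included: the tidy trait tables are designed to feed standard
  statistics tooling.
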