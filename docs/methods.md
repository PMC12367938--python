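# Methods

This note documents the models implemented in `tetragp`, the assumptions
behind the synthetic-data generator, the numerical choices made where the
methodology left them open, and the known limitations.

## Simulated breeding populations

The generator (`tetragp.simdata`) emulates the structure of a commercial
autotetraploid potato breeding panel at the first replicated field stage.

**Genomes and meiosis.** Founders carry four haplotypes per chromosome;
allele frequencies are drawn per marker from Beta(2, 2), with a per-segment
logit shift (SD 0.15 by default) that induces mild differentiation among
the four market segments (global F_ST ≈ 0.02–0.03 at the default, the
order of magnitude reported for real potato panels). Meiosis is
bivalent-only: the four homologs pair at random into two bivalents,
recombination follows the Haldane map function within each bivalent, and
one chromatid per bivalent enters the diploid gamete. Double reduction is
deliberately excluded — the dominance model distinguishes exactly the
three heterozygote classes of bivalent segregation, and double reduction
would add a phenomenon the downstream models never use. Under this scheme
a duplex selfing (AAaa × AAaa) segregates gametes AA:Aa:aa = 1:4:1, which
the tests verify against exact enumeration.

**Families and metadata.** Clones arise as full-sib families (default 171,
sizes geometric with mean ≈ 6.2, clipped to 1–38, matching a panel of
≈ 1,000 clones) from founder pairs of the same market segment; families
are assigned to four segments with weights 0.36/0.25/0.25/0.14 and to
three breeding companies. Eight check clones are simulated from random
founder crosses and shared across companies.

**Traits.** A trait is a set of QTL drawn from the marker panel with
additive effects `a ~ N(0, ·)` rescaled so the realized panel variance
equals the declared additive variance exactly, plus per-class dominance
deviations (d1, d2, d3 per QTL) rescaled to the declared dominance
variance, plus optional per-segment mean shifts (free parameters; the
field only reports that segments cluster, not how strongly traits differ,
so defaults were chosen to give Q_ST values inside the published 0–0.74
range). Ordinal traits are generated on a latent continuous scale and then
rounded and clipped to 1–9; percentages are clipped to 0–100; kilogram
traits additionally record planted/missing plant counts and a raw yield
that inverts the 16-plant normalisation exactly.

**Trials.** Entries appear once per environment of their own company;
checks appear eight times per environment with at least one per block.
Blocks hold near-square row×column grids. Plot values follow the
adjustment model below, with true genotype-by-environment deviations drawn
for *all* clones (the analysis model can only estimate them for checks;
the generator records them for diagnostics) and heteroscedastic residuals
per environment. When no per-environment residual variances are given they
are calibrated from the target entry-mean heritability: with J
environments per entry, `h² = σ²_g / (σ²_g + (σ²_gxe + σ̄²_ε)/J)` solved
for `σ̄²_ε`, spread ±30% across environments. One environment can be split
into two trials to exercise the check-based trial correction.

**Discard labels.** An early-stage selection index (standardised weighted
true genetic values plus N(0, 1) noise) ranks entries; whole families with
the lowest mean index are discarded first (status 2, default 6.4% of
clones), then the worst clones within retained families (status 1) up to a
total discard fraction of 31%, keeping at least one clone per family —
the proportions of the motivating breeding programme.

**What the simulation does not capture.** Real dosage calling error and
array artefacts; linkage-disequilibrium structure from many breeding
cycles (one generation from founders only); selection on phenotype rather
than true genetic value in the discard labels; spatial field trends beyond
row/column effects; multi-year genotype-by-year structure. Passing tests
therefore demonstrate correctness and qualitative behaviour of the
*methods*, not quantitative transfer of accuracy values to real data.

## Phenotype adjustment

The fixed pipeline per trait is: yield normalisation → check-based trial
correction → mixed-model fit → outlier removal (|standardized residual| >
3.5, strict) and refit → boundary-mixture LRT for the block variance
(α = 0.05; 0.5·χ²₀ + 0.5·χ²₁ null) with check-based block correction when
significant → final fit for AEMs and ν̂ → entry-variance model → h².
Outlier removal and block correction are applied once, not iterated.

The two-group check correction subtracts the absolute check-mean
difference from the higher group; with more than two groups (blocks) each
group is aligned down to the minimum check mean — the natural
generalisation of the pairwise rule, chosen so corrected check means are
equal and no observation is ever shifted upward.

`ν̂` is the exact mean over all entry pairs of Var(AEM_i − AEM_k),
computed in closed form from the entry block C of the fixed-effect
covariance: `ν̂ = 2[(n−1)tr C − (1'C1 − tr C)]/(n(n−1))`. Sampling pairs
is unnecessary at any panel size.

### REML engine

`tetragp.reml.MixedModel` fits Gaussian mixed models with factor random
effects and group-wise heteroscedastic residuals on Henderson's mixed
model equations. Two EM sweeps stabilise the start, then
average-information updates with step-halving take over; a step that
leaves the parameter space or lowers the restricted likelihood falls back
to EM. Variance components that collapse below 10⁻⁶·Var(y) are pinned at
an effective zero (10⁻⁸·Var(y)) and released if their score turns
positive — without pinning, boundary components stall the AI iteration.
Convergence is a relative parameter change below 10⁻⁸ (200-iteration cap);
the heavy simulation studies use 10⁻⁶, which changes h² estimates by less
than 10⁻³. Singular coefficient matrices raise immediately. The engine is
validated against closed-form balanced ANOVA estimators, brute-force
dense-V restricted likelihoods, and grid searches around the optimum.

## GBLUP

`fit_gblup` maximises the restricted likelihood of
`V = σ²_a G_A (+ σ²_d G_D) + σ²_ε I` with only an intercept fixed, via
L-BFGS-B on log-variances with analytic gradients. Genetic variances that
end below 10⁻⁷·Var(y) are truncated to exactly zero, so a model carrying
an unsupported dominance term reproduces the additive model bit-for-bit.
Validation-set clones are predicted by the conditional-expectation
identity `â_VS = σ²_a G_A[VS,TS] V⁻¹(y − μ̂)`, algebraically identical to
the joint mixed-model equations but cheaper per replicate; with dominance
in the model the reported GEBV is the sum of additive and dominance
values. A replicate whose covariance has reciprocal condition number
below 10⁻¹² at the optimum is canceled rather than fitted; ill-conditioned
points merely *visited* during optimisation are smoothed with a diagonal
bump so the line search keeps curvature information.

Prediction accuracy divides the AEM–GEBV correlation by √h², with h² the
trait's pipeline estimate computed once on the full data (not per fold).
A cross-validation replicate's PA is the mean over its five folds; the
pooled-prediction variant is reported alongside.

**Model comparison.** `compare_models` runs additive and
additive-dominance GBLUP on identical folds and reports the paired t test
two ways: two-sided, and one-sided for an *improvement* of the dominance
model — the direction in which the scientific question ("does modelling
dominance help?") is posed. The distinction matters: across CV replicates
of one dataset, an unneeded dominance component produces a tiny but
systematic overfitting penalty (mean PA difference ≈ −0.003) that a
two-sided test flags as "different" while the improvement test correctly
calls "no better". PA differences below 10⁻⁶ are treated as exact ties.

## Scenario engine

Every scenario draws TS and VS as disjoint clone-id sets, runs GBLUP per
replicate, and attaches He(TS), He(VS), Nei distance, and AEM variances.
Percent-to-count conversions round half away from zero. Selection
("top x% of trait values") operates on AEMs, since selection in a breeding
programme acts on evaluated performance. Stratified replacement divides
the full phenotypic range (min–max) into ten equal windows and draws
round-robin from windows unoccupied by the TS, topping up from the general
pool if they run dry. Rank-sum selection ranks per trait with ties broken
by clone-id order (documented, deterministic) and sums ranks. The
discard-inclusion scenario keeps per-family TS contributions constant by
swapping members for status-1 clones of the same family, resampling the
replicate (with a log note) when families lack discards. Canceled
(singular) replicates are counted and excluded from medians.

## Diversity statistics

Tetraploid expected heterozygosity is `He = (1/m) Σ (1 − p⁴ − q⁴)`
(maximum 0.875 at p = ½), with frequencies from mean dosages including
imputed values — the same convention as the relationship matrices. Nei's
standard distance is `−ln(J_ab/√(J_a J_b))` with identities averaged over
loci. F_ST is Nei's `(H_t − H_s)/H_t` with H_t from the pooled panel and
H_s the unweighted mean group He; the pairwise version restricts to two
groups and uses the same construction (a deliberate dialect choice rather
than a method-of-moments estimator, since only the estimator family is
pinned down). Q_ST is `σ²_m/(σ²_m + σ²_m(c))` from among/within-segment
variance components; the analysis scripts estimate these by a one-way REML
fit on entry AEMs.

## Problem sizes

The verification experiments use deliberately chosen desk-scale sizes:
h²-recovery runs 20 independent 800-entry studies in two environments
(residual variances calibrated for h² = 0.80); the truncation study uses
1,000 clones, TS = 200, 50 replicates per cell; the dominance-null study
150 clones × 400 markers, 10 CV replicates, 20 runs; outlier detection 120
entries in four environments, 100 seeds (four environments keep the fixed
clone effect from absorbing more than a quarter of a contaminant). The
analysis scripts default to a ~440-entry panel with 1,500 markers and
scale to the full 171-family, five-environment design via `--full`.

## Known limitations

- Single-trait mixed models throughout; no multi-trait GBLUP or
  spatial-correlation (AR1×AR1) structures.
- No Bayesian whole-genome regression models.
- Relationship matrices use panel-internal allele frequencies; there is no
  external reference population.
- The simulator produces one meiotic generation from founders, so
  long-range LD and inbreeding accumulation over cycles are absent.
- Prediction accuracies on simulated data characterise the method's
  qualitative behaviour; they are not calibrated to any real panel.
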