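# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the open design decisions behind `forageval`.

## Trial model and the synthetic generator

The package targets a balanced multi-environment trial: genotypes G,
locations L, years Y, with `r` replicate plots per G×L×Y cell laid out as
a randomized complete block design. The generator draws one value per
plot and trait from

    value = baseline + g(G) + l(L) + y(Y) + interaction(levels) + block + ε,
    ε ~ N(0, residual_sd²),

with all effects additive. Noise is independent Gaussian per plot and
trait: the source trial reports only means ± SE, so no cross-trait or
spatial covariance is claimed, and none is simulated (cross-trait
correlation would mainly affect the entropy weights, which is why the
ranking tests are interpreted qualitatively). An optional shared block
effect per replicate within an environment is available but defaults to
zero — block variance is never quantified in the reports this emulates.
Values below a trait's `lower_bound` (0 for percentages) are clipped and
the clipping logged.

`stay_green_preset()` fixes the study conditions: 2 genotypes (control CK
vs stay-green mutant SG) × 2 locations (cool high-altitude HZ vs warm
dry-hot valley YM) × 2 years × 3 replicates, 13 traits (six biomass/yield
traits, thousand-grain weight, four nutritional components, ADF, NDF).
Signed effects encode the qualitative structure of such trials:

- SG exceeds CK on every benefit trait and sits below CK on ADF/NDF; the
  genotype main effect is **two within-cell residual SDs** on every trait,
  large enough that a 24-plot trial detects it at p < 0.05 with high
  power (the pervasive-significance regime the evaluation is designed for);
- YM out-yields HZ; HZ has lower fiber and higher protein/starch/fat, so
  feeding value is higher at HZ;
- yields are higher in 2024, quality components in 2023.

Baselines and residual SDs are realistic field magnitudes for dual-purpose
oats (e.g. fresh forage yield 30 t/ha ± 1.5, ADF 32 % ± 1, NDF 52 % ± 1.2);
they were chosen once when the preset was written. No interaction effects
are included by default, so the preset's noiseless cell means are exactly
additive — which pins down the downstream expectations (parallel
interaction plots, zero ecovalence) used by the cross-module tests.

What the generator does *not* emulate: spatial field trends, within-plot
subsampling (one value per plot is emitted; the number of plants averaged
per plot is not modelled), measurement error structure of NIRS
predictions, and climate-driven year effects beyond a constant shift.
Passing tests therefore demonstrate correctness of the *statistical
machinery* under the stated model, not robustness to real-data pathologies.

## Feeding-value indices

DMI = 120/NDF (% body weight), DDM = 88.9 − 0.779·ADF, TDN = 82.38 −
0.7515·ADF (% DM), RFV = DMI·DDM/1.29, RFQ = DMI·TDN/1.23 (unitless).
Indices are computed per biological replicate and only then averaged —
computing them on cell means would bias the nonlinear DMI term. No
internal rounding; display layers round to 2 dp. The linear DDM/TDN
approximations go non-positive for ADF beyond ≈114/109 % DM; such values
are passed through with a warning rather than floored, because inventing
a floor would silently change downstream indices. Alternative RFQ
equations (legume variants, NDF-digestibility forms) are out of scope.

## ANOVA

The trial is analysed with **balanced fixed-effects factorial ANOVA**.
Reports of this kind often cite "linear mixed models" without naming the
random terms; for a balanced complete design the fixed-effects F-tests
coincide with the obvious mixed formulations and no variance components
are reported to compare against, so the fixed-effects decomposition is
the defensible, exactly-reproducible choice. It is computed from marginal
means by inclusion–exclusion: S(T) = n_T Σ (x̄_T − x̄)² over the level
combinations of factor subset T, SS(T) = Σ_{S⊆T} (−1)^{|T\S|} S(S),
residual SS by subtraction, F = MS(T)/MS(residual), upper-tail F p-values.
Unbalanced or incomplete inputs are rejected explicitly (no Type II/III
machinery). All-constant inputs report NaN for F and p. The test suite
verifies every term SS against an independent OLS sequential-projection
oracle (statsmodels `anova_lm`) to 1e-8 relative on random datasets.

Per-environment analysis treats each location–year combination as one
environment and runs one-way genotype ANOVA within it. Tukey HSD uses the
pooled within-group mean square, Tukey–Kramer standard errors and the
studentized-range distribution; the compact letter display is the
standard insert-and-absorb algorithm with letters assigned in descending
order of group mean ('a' = best), matching agronomy reporting convention.
No multiple-testing correction is applied across traits. Significance
stars: ns > 0.05, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.

## Stability

CV (%) is 100·sd/mean with the sample (n−1) sd, computed per
genotype–location–year replicate group by default. Wricke's ecovalence is
computed on the cell-mean table (it is defined on the two-way means
table): W_i is the row sum of squared double-centering residuals, so
Σ W_i equals the interaction SS by construction, and adding a constant to
any row or column leaves W_i unchanged. The default layout is
**genotype–year entries × location environments**, reproducing the
common genotype–year stability panel; genotype × (location–year) is the
documented alternative via the `entry_axis`/`env_axis` arguments. Note a
structural consequence of two-column tables: within each year the two
entries' W_i are forced equal (residuals are antisymmetric), which is a
property of the layout, not a bug. Interaction series flag a crossover
whenever two entry trajectories change sign of their difference between
consecutive environments.

## Multi-criteria ranking

**Decision matrix.** Alternatives are the G×L×Y treatments (8 under the
default design); criterion values are cell means. Default criteria follow
the key-trait selection of comprehensive oat evaluations: TGW, grain
yield, fresh and dry forage yield (group *yield*), starch and protein
(group *quality*), plus two *stability* cost criteria whose construction
is an open design point resolved as follows: `CV` is the mean replicate
CV over the trait criteria for that cell, and `Wi` is the mean ecovalence
**share** (fraction of interaction SS, hence unitless and averageable
across traits of different scales) of the treatment's genotype–year entry.

**Entropy weights.** Columns are direction-aligned by min-max scaling
(benefit: (x−min)/(max−min); cost: (max−x)/(max−min)) before the entropy
computation — the pre-treatment is not standardized in the literature, so
it is explicit and testable here. Constant columns get exactly zero
weight; if every column is constant the weights fall back to uniform with
a warning.

**AHP.** Weights are the normalized principal eigenvector obtained by
power iteration (tolerance 1e-12); the geometric-mean approximation is
not used as the implementation but agrees closely on consistent matrices.
CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with Saaty's canonical RI table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45 for n = 1..9); CR < 0.1
is the reliability gate. The default judgments (yield:quality = 3,
yield:stability = 5, quality:stability = 3) give weights
(0.637, 0.258, 0.105) with CR ≈ 0.033.

**Combination.** The default *hierarchical* scheme uses every stated
expert judgment and invents none: AHP allocates weight across the three
criterion groups — exactly the level at which the pairwise judgments
exist — and entropy allocates within each group (renormalized to the
group's AHP weight). A *multiplicative* scheme (w ∝ entropy·expert,
renormalized) is available when per-criterion expert weights are supplied.

**TOPSIS.** Vector normalization r_ij = x_ij/‖x_·j‖, weighting, ideal =
column max (benefit) / min (cost), anti-ideal reversed, Euclidean
distances, closeness d⁻/(d⁺+d⁻), dense ranks on descending closeness
(ties share a rank and are logged). Rank order is invariant to positive
rescaling of any criterion column.

**Degenerate runs.** On noiseless data the CV and Wi columns are exactly
constant (zero): a constant criterion cannot discriminate, and an
all-zero one has no vector norm. `topsis_rank` treats a zero-norm column
with positive weight as an error (its direction would be meaningless),
while the model layer drops constant criterion columns with a warning
before weighting and renormalizes the AHP group weights over the
surviving groups. Relatedly, two floating-point guards keep degenerate
inputs exact: replicate sets with identical values report CV = 0 (naive
sd of identical floats is ~1e-15, not 0), and an interaction SS below
1e-20 of the table's total sum of squares is treated as exactly zero so
that additive tables do not yield rounding-noise ecovalence shares.

## Pipeline and determinism

One RNG (`numpy.random.default_rng(seed)`) is created per run; stages
never reseed. All CSV output is written at full float precision; only the
human-readable report rounds. The run manifest records the config echo,
seed, package versions and a SHA-256 digest per output file, so a re-run
with the same config is verifiable byte for byte.

## Problem sizes used in the test suite

Recovery and calibration checks run at desk scale: 500 simulated trials
for the genotype-effect power/recovery check (single trait, 24 plots
each), 200 trials for the SG-vs-CK ranking frequency, 200 random tables
for ecovalence conservation, 100 random datasets for the ANOVA oracle
comparison, and a 10 000-replicate design for the generator's mean-effect
Monte-Carlo check.

## Known limitations

- Fixed-effects ANOVA only; no REML variance components, no unbalanced
  designs, no spatial models.
- Stability statistics are descriptive; no Finlay–Wilkinson, AMMI or GGE
  machinery.
- Single expert judgment set; no group-AHP aggregation, no fuzzy TOPSIS.
- The generator's independence assumptions (see above) mean simulation
  results quantify machinery correctness, not field predictivity.
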