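# Methods

## Compositional preprocessing

LC-MS intensity tables carry no absolute scale, so all statistics operate
on centred log-ratio (CLR) values: per sample,
`clr_i = ln x_i − (1/m) Σ_j ln x_j`. The natural logarithm is used; the
base only rescales every CLR value by a constant and leaves p-values and
acrophases unchanged. CLR columns sum to zero, making Euclidean geometry
(and therefore PCA, Aitchison distances and OLS) applicable.

Zeros are below-detection-limit artefacts, not true absences. They are
replaced by `const_factor × min positive value of the feature`
(`const_factor` default 0.5, the common half-minimum detection-limit
surrogate; the replacement is per feature because detection limits differ
across metabolites). A feature that is zero in every sample has no valid
replacement constant and raises an error rather than being dropped
silently. Alternative imputation schemes (multiplicative lognormal,
Bayesian-multiplicative) and other log-ratio transforms (ILR/ALR) are out
of scope.

One consequence of closure worth knowing: the CLR subtracts the per-sample
mean log signal, so a strongly coherent rhythm in one feature subset leaks
a small anti-phase rhythm (amplitude ≈ subset resultant / panel size) into
every other feature. With the generator's uniform acrophases the leak has
amplitude ~0.05 CLR units and is negligible; with highly phase-clustered
panels it is a real property of CLR analysis, not an artefact of this
implementation.

## Cosinor model

Fixed-period (`P = 24` h) single-harmonic regression per feature and
group: `y = M + β_s sin(ωt) + β_c cos(ωt)`, `ω = 2π/P`. Four timepoints
cannot identify a free period, so P is never estimated. Amplitude is
`√(β_s² + β_c²)`; the acrophase `(P/2π)·atan2(β_s, β_c) mod P` is the peak
time of the fitted curve in ZT hours on `[0, P)` and is reported as
undefined (NaN), never 0, when the amplitude falls below 1e-12.
Rhythmicity is the F-test of the sine/cosine pair against the
intercept-only model (2 numerator df, within-group residual df). The
multi-group design uses cell-means coding (per-group intercept/sin/cos),
so per-group estimates equal separate per-group OLS fits while the pooled
model supplies interaction contrasts. Perfect (zero-residual) fits are
flagged `degenerate` with the limiting p-value rather than raising, so
noiseless recovery checks run end to end. Designs need ≥3 distinct
timepoints per group; rank deficiency raises an identifiability error.

## Differential rhythmicity

A rhythm difference between groups a and b appears in the interaction
contrasts `β_s(a) − β_s(b)` and `β_c(a) − β_c(b)`, each tested with a
t-statistic using the pooled residual variance. With two groups the Tukey
adjustment is exactly the identity; with k ≥ 3 each contrast p is
`P(Q_{k,df} ≥ √2·|t|)` from the studentized range. Per feature the two
component p-values are Bonferroni-doubled and the smaller (capped at 1) is
the feature's differential-rhythmicity measure; Benjamini–Hochberg runs
across features on that measure and features with q strictly below 0.1 are
called. The composition order is configurable
(`correction_order="bh_then_bonferroni"` BH-adjusts each component across
features first); the default corrects within feature first, the more
conservative reading. No gating on marginal rhythmicity is applied: a
feature can be differentially rhythmic without a significant rhythm in
either group alone (an optional restriction is available in the summary
stage instead).

A 12 h shift at equal amplitude negates both harmonic coefficients, giving
the maximal interaction contrast `2A·sin(π·Δφ/P)` among all shifts — the
design's strongest detectable signal.

## Amplitude permutation test

The statistic is `|A_a − A_b|` from per-group fits. The null is built by
permuting group labels within timepoint strata, preserving the sampling
design; when cage identifiers are supplied (the pipeline always supplies
them) whole cages exchange labels instead of individual animals, so
within-cage correlation survives into the permutation null. Animal-level
permutation under a cage random intercept of SD 0.2 measured ~9% false
positives at α = 0.05 on simulation; cage-blocked permutation measured
5.1% under the exchangeable null and 3.4% under a 12 h phase shift
(slightly conservative there, because mixing antiphase groups inflates
the permuted statistic). The p-value is the add-one estimator
`(1 + #{perm > observed})/(1 + n_perm)` counting strict exceedances, so
the attainable minimum `1/(1+n_perm)` is reached whenever the observed
statistic strictly dominates, and `n_perm ≥ 99` is required.

## Cohort-level structure

PERMANOVA uses Anderson's pseudo-F on squared distances with significance
by label permutation; the pipeline applies it to Aitchison distances
between cage-mean CLR profiles (means of zero-sum vectors are zero-sum),
with cage — the shared-housing unit — as the exchangeable unit. Units are
already cage-aggregated, so permutations are unrestricted across units.
When the number of distinct label assignments is at most `n_perm` the null
is enumerated exhaustively and p is the exact fraction of assignments
(observed included) reaching the observed F; otherwise `n_perm`
(default 9,999) Monte-Carlo permutations with the add-one estimator. The
grouping term is selectable (`group`, `time`, `group_time`): a pure phase
inversion leaves group marginal means unchanged over a balanced cycle, so
the `group` term is expected null on such data while `group_time` carries
the structure. PCA operates on feature-centred CLR samples via SVD.

The cage-sensitivity check refits `y ~ group*(sin + cos)` per feature by
OLS and by a linear mixed model with a cage random intercept (REML;
L-BFGS with a derivative-free Powell fallback at the zero-variance
boundary) and reports both interaction coefficient pairs and their
differences. When cages are nested in group × timepoint cells with equal
sizes, every fixed-effect column is cage-constant and the two point
estimates coincide exactly; imbalance or cage-confounded designs move
them apart. Non-convergence is flagged and the OLS result still returned.

## Synthetic-data generator

The generator emulates the study design it is meant to stress:
`log y = mesor + A·cos(ω(t − φ)) + u_cage + ε`, exponentiated to strictly
positive abundances, with defaults

| parameter | default | meaning |
|---|---|---|
| `n_features` | 120 | annotated metabolite panel size |
| `groups` | CV, ABX | conventional vs microbiota-depleted |
| `timepoints_h` | 5, 11, 17, 23 | ZT sampling times |
| `n_per_cell` | 8 | animals per group × timepoint (study reports 7–8) |
| `cage_size` | 3 | animals per cage (study: 2–4), nested in group × timepoint |
| `frac_rhythmic` | 0.5 | features with a 24 h rhythm |
| `frac_shifted` | 1/3 of panel | rhythmic features with a between-group phase shift |
| `acrophase_shift_h` | 12 | phase offset of the shifted subset, amplitude preserved |
| `amplitude_log` | 1.0 | log-scale amplitude (scalar or uniform range) |
| `mesor_log`, `mesor_sd` | 8, 1 | per-feature mean log abundance |
| `sigma_noise` | 0.5 | residual log-scale SD |
| `sigma_cage` | 0.2 | cage random-intercept SD |
| `zero_rate` | 0.02 | entries zeroed completely at random |

Rhythmic acrophases are uniform on the circle; shifted features offset the
later group's phase by `acrophase_shift_h`. Cages are nested within
group × timepoint cells (cage-mates culled together; the last cage of a
cell may be smaller), and the cage intercept is drawn independently per
(feature, cage) — a sample-level intercept shared across features would be
removed exactly by the CLR and could never be studied downstream. Zeros
are injected completely at random, a deliberate simplification of
intensity-dependent censoring that suffices to exercise the replacement
rule. Equal seeds give bit-identical output. `generate_null_dataset`
forces identical generating parameters in both groups.

What passing tests on this generator do **not** show about real data: the
generating model matches the analysis model (single harmonic, log-normal
noise), zeros are missing-completely-at-random rather than
intensity-censored, acrophases are uniform rather than clustered around
the light/dark transitions, and features are generated independently
before closure. Recovery and calibration results are therefore best-case
statements about the machinery, not about LC-MS reality.

## Calibration regimes and problem sizes

The OLS cosinor F-test is exactly calibrated when residuals are i.i.d.;
a nonzero cage intercept makes it anticonservative at the animal level
(measured KS ≈ 0.16 from uniform at `sigma_cage = 0.2`), which is
precisely why the cage-mean PERMANOVA and the cage-sensitivity refit
exist. Calibration checks therefore run at `sigma_cage = 0`, the regime
where uniformity is the correct expectation.

Test-suite simulation sizes were chosen to keep the default run fast
while leaving comfortable statistical margins: 10,000 features for
uniformity KS bounds of 0.02, 50 seeds × 120 features for null
calibration (per-seed KS guarded at the 0.1%-level critical value, since
150 per-seed checks run and the expected KS distance of 120 uniform draws
is already ≈ 0.08), 20 seeds for power/shift recovery and 5 × 120
features × 199 permutations for amplitude calibration. The acceptance
script uses 10/10/5 seeds for the same quantities and 9,999 PERMANOVA
permutations.

## Known limitations

- The period is fixed; mis-specified periods bias amplitude and acrophase.
- The differential test assumes homoscedastic residuals across groups.
- Cage-blocked permutation requires cages nested within timepoint strata,
  as in the emulated design.
- The mixed-model refit estimates a single variance component; crossed or
  multi-level housing structures are not supported.
- Group-level circular-mean shifts are only meaningful when acrophases are
  concentrated (resultant length well above 0); for diffuse phase
  distributions use per-feature circular differences, as the analysis
  scripts do.
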