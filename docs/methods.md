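# Methods

This note documents the models, algorithmic choices and limitations of
`nmrmetab`, in the order the pipeline runs.

## Synthetic serum cohorts

The generator is a forward model of a one-dimensional ¹H-NMR serum
spectrum, not an FID simulator: each metabolite contributes Lorentzian
multiplets whose total integrated area is proportional to its
concentration, and nuisance structure is added on top. Per sample,

```
intensity(δ) = d · Σ_m c_m Σ_r a_r · multiplet_r(δ) + baseline(δ) + ε(δ)
```

* `d` — global dilution factor, log-normal with log-sd `dilution_sd`
  (default 0.1). This is the nuisance PQN is designed to remove.
* `c_m` — per-sample concentration, log-normal around the group mean with
  CV 10% (mean-preserving). No per-animal dispersion is published for this
  design, so 10% is a conventional serum-metabolite biological CV; it is a
  stated default, not an inferred one.
* `multiplet_r` — the resonance's lineshape. Multiplicity codes are
  rendered with a fixed convention since only the codes are tabulated:
  s = 1 line; d = 2 equal lines; t = 1:2:1; q = 1:3:3:1; dd = 4 equal
  lines with couplings J and 0.4 J; m and br = one Lorentzian broadened to
  3× the nominal linewidth. J is fixed at 7 Hz, converted to ppm at the
  599.808 MHz proton frequency. Nominal linewidth: 0.002 ppm HWHM.
* `baseline` — a 1–3-cycle sinusoid with random phase, amplitude 0.5
  intensity units (≈1% of a typical peak height), emulating residual
  post-correction baseline drift.
* `ε` — i.i.d. Gaussian noise, sd 0.5 intensity units.

The ppm grid is 0.5–9.0 ppm with 16384 points, stored ascending. Group
mean concentrations are the fixture base levels scaled by fold changes
from the effect tables; contrasts are labelled `CASE_vs_REF` and chain
(the treatment group's levels are the disease group's levels times the
treatment fold changes), so a three-group WKY-N/SHR-N/SHR-H cohort is
specified by the two published contrasts. A group named in no contrast
(e.g. a low-dose arm, for which no per-metabolite effects are tabulated)
falls back to reference levels; the default demo therefore omits it.
Base levels (arbitrary units) were chosen once to give realistic relative
serum peak sizes (glucose ≫ amino acids); fold changes, not absolute
levels, carry the signal.

What the generator does **not** emulate: peak-position jitter (no
mis-alignment, so no icoshift step), multiplet roofing, water-suppression
residuals, phase errors, or correlated (pink) noise. Passing tests
therefore demonstrate correctness of the analysis machinery under the
stated noise model, not robustness to chemical-shift drift.

### Integration shifts

Per-metabolite integrals use a fixed window of ±0.02 ppm around one
designated resonance. The publication marks its integration shifts in
boldface, which does not survive text extraction; the default here is the
first listed shift, with fixture overrides — chosen a priori from the
shift table for isolation — for four metabolites whose first shift sits
under a stronger neighbour: histidine → 7.07 (3.99 collides with serine
3.98), creatine → 3.93 (3.04 collides with lysine 3.03), myo-inositol →
4.07 (3.28 collides with betaine 3.27), lactate → 4.11 (1.33 collides
with the broad lipoprotein resonance at 1.31). Remaining window overlaps
(e.g. glutamine/methionine at 2.14) are flagged with a warning and left
in place: overlapped resonances genuinely share signal in 1D spectra.

## Preprocessing

**Exclusion.** Points with δ in [4.33, 5.50] ppm (water and neighbouring
signals, including the glucose 5.24 and lipid 5.31 resonances) are
removed before binning.

**Adaptive binning.** The cited binning code is not available, so the
following reading of "adaptive binning at a 0.015 ppm average" is used:
uniform seed boundaries at the target spacing are each moved to the
lowest point of the cohort-mean spectrum within ±40% of the target width
(ties resolve to the seed, so featureless regions stay uniform), then
bins narrower than 25% of the target are merged into their narrower
neighbour. Boundaries are grid indices, so per-sample bin integrals sum
exactly to the trapezoidal integral of the retained trace, and the
retained range on either side of the excluded window is binned
separately (no bin straddles it).

**PQN.** Rows are first scaled to the cohort-median total integral, then
divided by the median feature-wise quotient against the reference
spectrum — the median spectrum over all samples by default, or over a
named control group. Quotients use only features whose reference value
exceeds 1% of the reference's median positive value, keeping
noise-dominated and negative bins out of the dilution estimate. The
reported `dilution_estimate` (total-integral factor × quotient) recovers
injected dilution factors essentially exactly on pure-dilution cohorts.
Two caveats are documented rather than hidden: (i) PQN assumes most
features are unchanged between groups — when nearly every metabolite
carries an effect, part of the median effect is absorbed into the
quotient, biasing fold changes toward 1 (visible as a few-percent bias in
the recovery studies); (ii) PQN is exactly idempotent only when rows are
scalar multiples of one profile; on noisy cohorts a second application
moves values by < 1%.

**Scaling.** Columns are mean-centered and divided by the square root of
the column standard deviation (pareto), so the post-scaling variance
equals the pre-scaling sd. Constant columns are set to zero and flagged,
never dropped, keeping feature indices aligned with bin metadata.

## Multivariate models

PCA is a thin wrapper over a full-SVD decomposition. OPLS-DA follows the
orthogonal-signal-correction construction: with class membership coded
−1/+1, k y-orthogonal components are extracted and removed from X, then a
single predictive PLS component is fitted to the filtered matrix. With
k = 0 the predictive component is exactly a one-component PLS1 fit, which
the tests verify against an independently written NIPALS oracle. The
predictive weight is signed so the second-listed class has a positive
mean score. R²X partitions exactly into predictive + orthogonal +
residual parts; predictive and orthogonal scores are mutually orthogonal
(both identities tested to 1e-8/1e-6).

**Q².** Repeated stratified two-fold cross-validation (default 7
repeats). Within each training fold, column means and the orthogonal
components are re-estimated from the training half only, so no
information leaks from held-out samples. Q² = 1 − PRESS/TSS accumulated
over both folds, averaged over repeats. The repeat count is a
convention — the source protocol states "repeated twofold" without a
count.

**Permutation test.** Labels are permuted n times (default 2000) and each
relabelling is scored by the same CV procedure with the same internal
seed, giving the add-one estimator p = (1 + #{Q²_perm ≥ Q²_obs})/(n + 1).
Because the scoring function is identical across relabellings, the
p-value is uniform under exchangeable nulls (verified by a KS test over
200 simulated null datasets). Note that with exactly balanced classes the
label-swap permutation yields an equivalent model, so the achievable
p-value floor is effectively 2/(n + 1) in balanced designs.

**VIP.** Computed over the predictive component only (the discriminant
reading): VIP_j = √p·|w_j| with unit-norm weights, so mean VIP² = 1
exactly; a total-model variant weighting components by explained class
variance is available and nearly coincides, since orthogonal components
carry almost no class variance. For metabolite-level selection the model
is fitted on the binned matrix and each metabolite inherits the maximum
bin VIP inside its integration window — importance is a property of
spectral variables, and a 31-column metabolite matrix in which most
columns carry true effects cannot have most VIPs above 1 (the mean-VIP²
identity caps it), whereas the binned model recovers >90% of large
injected effects at a <10% false-selection rate in the test suite.

## Biomarker accounting

Selection uses raw p < 0.05 (strict) and VIP > 1 (strict): the published
tables include a p = 0.047 entry, so raw rather than BH-adjusted p
reproduces them; BH-adjusted values are computed and reported alongside.
The treatment-biomarker rule is selection in both contrasts **plus**
(FC_disease − 1)(FC_treatment − 1) < 0. The reversal requirement is an
inference: the published 13-metabolite list excludes four metabolites
significant in both contrasts whose changes do not flip direction, and
the sign-flip criterion reproduces the list exactly; the plain
intersection (17 members) is always returned alongside for transparency.
Metabolite names are matched case-insensitively through a small alias map
(e.g. LDL/VLDL ≡ VLDL/LDL).

## Pathways

Enrichment is the hypergeometric upper tail over a compound universe
(default: the union of all pathway nodes), BH-adjusted across pathways;
biomarkers outside the universe (e.g. the lipoprotein envelope) are
excluded with a warning. Impact is the sum of normalized betweenness
centralities ((n−1)(n−2)/2 normalization, undirected) of matched nodes
divided by the pathway total; on graphs with zero total betweenness
(complete graphs) uniform node weights are substituted so a full match
still scores 1. Screening keeps impact strictly > 0.1, sorted by impact
then enrichment p. The packaged graphs are hand-curated synthetic
sketches of ten named pathway maps plus five decoys — they reproduce the
computation, not any database snapshot, so absolute impact values are not
comparable to MetaboAnalyst output. The metabolite→protein map is
likewise a curated synthetic fixture over the ten hypertension-related
enzymes (TH, CBS, DDC, CTH, TYR, HDC, PLD2, AGXT2, KAT, ALT); DDC has no
edge because none of the listed biomarkers is its direct substrate.

## Orchestration and reproducibility

The pipeline validates its YAML configuration against a strict schema
(unknown keys rejected, all violations reported at once) with the
protocol's settings as defaults: exclusion 4.33–5.50 ppm, bin width
0.015 ppm, 2000 permutations, p < 0.05, VIP > 1, impact > 0.1. One global
seed derives per-stage seeds by hashing the stage name, so toggling one
stage never shifts another's random stream; every output file's SHA-256
is recorded in a run manifest, and repeated runs with one seed are
byte-identical.

## Problem sizes

The recovery studies simulate cohorts of 10 samples per group on the full
16384-point grid, averaging over 10 seeds per contrast; the null
calibration uses 200 replicates of 20-sample datasets at 99 permutations
with single-repeat CV, and algebraic identities are checked on 20 random
12×30 matrices. These sizes make every result in the test suite and the
acceptance script recomputable in a few minutes on one core.

## Known limitations

* Real-data model statistics (the published R²Y/Q² and PC variance
  fractions) are not reproducible without the raw spectra and are not
  targeted.
* PQN's fold-change attenuation under dense effects (above) means
  recovered FCs are expected to sit a few percent closer to 1 than the
  injected values.
* The adaptive-binning variant is one defensible reading of an
  underspecified method; boundary placement differs from other published
  "adaptive intelligent binning" objectives in featureless regions.
* No peak alignment is implemented; spectra are assumed
  chemical-shift-calibrated (TSP at δ 0.00).
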