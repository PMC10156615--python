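# Methods

This note documents the statistical and signal-processing choices behind
`soundmap`: what each stage computes, the assumptions it makes, the
parameters that matter, and what the synthetic cohorts do and do not
emulate.

## Rating cohorts and the synthetic generator

The pipeline's universal input is a dense participants × sounds ×
descriptors tensor of visual-analogue ratings in [0, 100], with a binary
diagnostic label per participant and optional trait scores. The default
battery is 32 sounds (8 per category: human oral/nasal, other human
actions, non-human, time-scrambled controls) × 17 descriptors (pain, rage,
disgust, hairs-on-end, headache, flinching, tingling, soothing,
pleasurable, annoyance, nausea, visual experiences, distress, body tension,
anxiety, discomfort, too loud).

Synthetic cohorts are drawn from a `ProfileSpec`:

- **Model.** Per participant and sound, a multivariate normal across
  descriptors (correlation `descriptor_corr`, SD `rating_sd`, default 18
  rating points) around `baseline_mean`, shifted for cases by
  `effect_d · rating_sd · g(severity)` and clipped to [0, 100]. Clipping is
  the simplest documented censoring model for bounded scale data; it biases
  realised effect sizes toward zero when means sit near the bounds, and a
  test measures this rather than hiding it (recovery is within ±0.15 of the
  target when means are ≥ ~1.5 SD from the bounds).
- **Severity.** Cases carry a latent severity ~ Uniform(0, 1); the scaling
  function `g` defaults to the identity, producing a continuum from
  near-control to full-effect cases (the gradient that classification
  counts track). A float value for `severity_slope` means constant scaling;
  `severity_slope=1.0` gives full-strength effects in every case and is the
  setting under which the closed-form AUC and effect-recovery checks hold.
- **Descriptor correlation.** Default: compound symmetry ρ = 0.5 within the
  aversive block and within the pleasant block (soothing, pleasurable,
  visual experiences), −0.3 between blocks. Real within-participant
  covariance is not publicly characterised, so these are configuration, not
  constants.
- **Default effect profile** (`default_profile`): per-sound magnitude
  (eating sounds ≈ 1.0–1.2, human actions 0.7, non-human 0.5, scrambled
  0.35, with two scrambled sounds at ≈ 0) times a per-descriptor weight
  (body tension 1.0 down to tingling 0.2; negative for the pleasant
  triple). Two sounds (nails on chalkboard, rusty swing) get a raised
  baseline for both groups to emulate universally disliked sounds with
  small group differences.
- **Determinism.** One seed governs a cohort; per-participant substreams
  are keyed by (group, index), so enlarging a cohort leaves existing
  participants bit-identical.

What the generator does *not* emulate: item-level response styles (end
aversion, anchoring), missing data, rating–audio coupling (ratings and
stimuli are generated independently), and any nonlinearity between trait
questionnaires and sound responses beyond the linear severity link. Passing
tests therefore demonstrate correctness of the machinery under a clipped
Gaussian response model, not distributional fidelity to any real cohort.

## Effect-size cartography

Cohen's d uses the pooled-SD (Student) form; with ~200 per group the
small-sample (Hedges) correction is < 0.5% and is omitted. Cells with zero
pooled SD or fewer than two observations per group are NaN and excluded
from summaries. Descriptor ordering comes from average-linkage
agglomerative clustering of 1 − Pearson r, computed by default on pooled
participant × sound observations (a per-sound-mean pooling is available;
the right level is genuinely underdetermined). Constant descriptors get
maximal distance (2) and join last, with a warning. Cross-group sound
rankings use average-rank ties and Spearman's rho, flagged against the
one-tailed critical value at N = number of sounds.

## Classification

Per sound: stratified k-fold CV (default 10; 5 for the smaller group-split
analyses), min–max rescaling fit on training folds only, a random forest
with one tuned hyperparameter (`max_features` over 2..8, chosen by nested
inner CV within each training fold by default; `tune="across"` tunes once
on the full data, which is cheaper and closer to an un-nested protocol).
AUC is computed on pooled out-of-fold case probabilities via the
Mann–Whitney identity — pooling is lower-variance than fold-averaging and
makes per-participant correctness flags well defined (probability ≥ 0.5 for
cases, < 0.5 for controls).

Numerical choices: 500 trees by default (stability at 17 features);
`min_samples_leaf=10` because fully grown trees produce noisy leaf
probabilities that measurably attenuate the pooled out-of-fold AUC below
the theoretical value on univariate-signal cohorts (on one informative
descriptor with d = 1 at n = 500/500, the pipeline's mean AUC is ≈ 0.744
against the Gaussian closed form Φ(d/√2) ≈ 0.760; fully grown trees lose
several more points). Tuning ties break toward fewer features per split.

Sensitivity/specificity labels follow the source analyses of this pipeline,
which call the proportion of *cases* correctly classed "specificity" and
the proportion of *controls* correctly classed "sensitivity"; this is the
reverse of standard usage, is deliberately preserved as the default for
comparability, and `convention="standard"` restores the conventional
orientation.

Permutation inference reruns the entire pipeline — rescaling, tuning, CV —
per label shuffle, so the null respects every data-dependent choice;
`p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm)` with n_perm = 1000 by
default (configurable down to 99 for desk-scale runs). FDR is
Benjamini–Hochberg step-up. The permutation engine is generic over the
statistic; its type-I calibration is verified with a cheap statistic at 200
null cohorts × 99 shuffles, since the exchangeability argument is
statistic-agnostic.

The aggregate classifier concatenates all sounds × descriptors into one
feature vector (544 in the default battery), with columns named
`sound:descriptor` so a fitted model can score new cohorts after aligning
columns by name.

## Cross-classification

Off-diagonal cell (A, B): the model for A is refit on *all* participants
(tuned, min–max scaler fit on A travels to B with clipping to [0, 1]) and
scored on the same participants' responses to B. Because train and test
share participants, transfer AUCs carry participant-level dependence and
are optimistic in absolute terms — on a literally duplicated sound the
default convention reproduces the training fit (AUC ≈ 1), not the CV
estimate. The optional split-half mode (train on half the participants' A
responses, test on the other half's B responses) gives unbiased transfer
estimates and is what the interchangeability tests use. Diagonal cells are
within-sound CV results and are not transfer estimates. Permutation nulls
shuffle labels once per permutation and refit every training sound
(n_perm = 199 by default), and FDR is applied jointly across all
off-diagonal cells; the matrix is never symmetrised.

## Feature selection

Per forest, out-of-bag permutation importance: for each tree, the error on
its out-of-bag samples minus the error after permuting one feature column
among those samples, averaged over trees. Per-tree bootstrap membership is
re-derived from the tree's random state exactly as the forest draws it; a
test pins this reconstruction against the forest's own reported OOB
decision function. Importances are summarised as mean and SD over
`n_forests` repeated forests (default 25 forests × 500 trees).

The retention rule is the thresholding step of the VSURF procedure: sort by
mean importance descending, fit a piecewise-constant regression tree of the
importance SD on the rank, take the minimum predicted SD as threshold, and
retain descriptors whose mean importance clears it. The tree uses
cost-complexity pruning with penalty `0.01 · var(sd)`, which makes the rule
scale-equivariant (scaling all importances by c scales the threshold by c
and leaves the retained set unchanged). The later interpretation and
prediction steps of the full procedure are out of scope. A fallback ranking
averages |d| down each column of the effect-size map; on univariately
injected signal the census and the |d| ranking agree.

## Cohort splits

Named presets ship the published thresholds: AQ ≥ 23 (broad autism
phenotype, within controls), hyperacusis self-report flag and sound-pain
factor > 3 on the 1–5 scale (within cases), mean ASMR-15 ≥ 2.5 after
excluding participants with SMS total > 50.5, and median splits for sensory
sensitivity and interoception. Median ties go to the low group
(deterministic). Splits default to 5-fold CV. Relabelling by the original
case/control labels reproduces the primary cartography exactly, and
additively layered profiles (e.g. a pain layer on top of the trigger
profile) surface in the split contrast while leaving the base case/control
map intact — both are tested.

## Auditory model and modulation ROI

The cortical representation is a simplified equivalent of wavelet-based
auditory models, sufficient for coarse bin-averaged ROI intensities:

1. **Filterbank.** 128 Gaussian band-pass filters on a 24-per-octave grid;
   centres are the geometric midpoints `440·2^((k−30.5)/24)` of the printed
   129-edge grid `440·2^((k−31)/24)` (edge 31 is exactly 440 Hz), spanning
   182–7142 Hz. FWHM equals one channel spacing. Analytic-signal envelopes
   are averaged in 5 ms frames. Requires a sample rate ≥ 2·f₁₂₇ ≈ 14.3 kHz.
2. **Compression.** `log1p(spec/floor)` with a fixed absolute floor
   (10⁻⁴), so intensity remains monotone in amplitude.
3. **Modulation decomposition.** Windowed (default 4 s, hop 2 s) 2-D FFT
   over (channel, time); each FFT cell is assigned to the nearest of 7
   spectral-modulation bins (0.125–8 cyc/oct) and 12 signed temporal bins
   (±1–32 Hz) on log-spaced grids, clamped at the ends (64 Hz content lands
   in the 32 Hz bin). The sign convention separates ripple directions:
   upward-moving ripples map to negative rates. The temporal-DC column —
   static spectral structure — is excluded: a stationary spectrum is not
   temporal modulation, and routing it into the ±1 Hz bins would swamp
   genuine slow modulation. Per-bin energy is obtained by masking the
   transform and inverting (which preserves the frequency axis, giving the
   4-D frequency × scale × rate × time array) and is reported as energy
   *density* per FFT cell so bins of different log-width are comparable.
   The bins partition all non-static cells, so density × cell-count sums to
   the window's non-static power (a tested Parseval identity). Inputs must
   provide ≥ 2 s of frames (1 Hz resolvability); only the first 30 s of a
   sound are analysed.
4. **ROI.** Mean intensity over channels with centres in [2500, 5500] Hz
   and temporal-modulation magnitudes in [1, 16] Hz, across all scales and
   windows. Magnitude (not signed) rate selection is used; the alternative
   reading (signed bins ±1..16) selects the same 10 of 12 bins.

Spearman correlations between per-sound ROI energies and mean ratings are
flagged one-tailed: exactly for n ≤ 10 (full enumeration of n! rank
permutations; the n = 8 critical value at α = 0.05 is 30/84 below 1, i.e.
0.6429) and by the Student-t approximation `c = t/√(df + t²)`, df = n − 2,
otherwise (0.344 at n = 24, 0.296 at n = 32).

## Time-domain scrambling

15 ms snippets are re-ordered by sorting indices keyed by
`index + Uniform(0, window/snippet)`, which bounds every snippet's
displacement by the 400 ms window *by construction*; the bound is asserted
on every run. Joins use 2 ms raised-cosine, amplitude-complementary
crossfades, so an identity permutation reconstructs the input exactly away
from the signal edges and RMS is preserved within 0.5 dB. This is a
faithful variant of the published scrambling approach, not a bit-exact
port (the original permutation scheme is not documented). The scramble
report quantifies what the operation preserves (long-term 1/3-octave
spectrum, within ~1 dB on noise) and what it removes (coherent temporal
modulation, measured as the drop in the rate marginal at the input's
modulation frequency).

## Problem sizes in the test suite

The suite exercises the statistical claims at desk scale, chosen once:
forests of 25–300 trees, 3–10 folds, cohorts of 20–500 per group depending
on the check (500/500 where the closed-form AUC comparison demands it; 200
cohorts × 99 permutations for type-I calibration; 10 replicate seeds for
feature-set recovery). Tolerances reflect the Monte-Carlo error of those
sizes, computed before freezing (e.g. AUC SE ≈ 0.05 on an 80-participant
test half).

## Known limitations

- Transfer AUCs in the default cross-classification convention are
  optimistic (shared participants); use split-half mode for unbiased
  estimates.
- The VSURF threshold tree is an sklearn re-implementation with a fixed
  cost-complexity penalty, not a port of rpart defaults; retained sets can
  differ from the R implementation in borderline cases.
- The auditory front end is a constant-Q Gaussian filterbank, not the full
  wavelet cortical model; absolute ROI energies are not comparable across
  implementations, only orderings and correlations.
- Ratings are modelled as clipped Gaussians; heavy floor effects (many
  exact-0 ratings) in real data are only crudely approximated.
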