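# Methods

This note records the models, parameter choices and numerical decisions
behind `neurolex`, and what the synthetic validation does and does not show.

## Word-complexity parameters

Words carry an abstract phonological decomposition: a sequence of syllables,
each an onset-consonant count, a nucleus-vowel count (≥ 1; diphthongs count
as one nucleus) and a coda-consonant count.  From this:

* **NoS** — the syllable count.
* **CVR** — total consonants / total vowels.  Computed phonologically; users
  with orthographic input should convert first, since letter counts and
  phoneme counts differ.
* **EoA** — a configurable linear penalty model over the three factor
  families that drive articulatory difficulty:
  `EoA = intercept − w_metric·[stress not word-initial] − w_cluster·(#
  consonant clusters of size ≥ 2) − w_gesture·(# articulatory gestures)`,
  with defaults (10, 1, 1, 0.25).  The published coefficient set of the
  clinical articulation model this emulates is not publicly printed, so the
  implementation keeps the model's inputs and direction while treating the
  weights as configuration; whether the original is strictly linear is
  unknown, and the linear form here is a declared approximation.  The score
  is undefined for words of more than three syllables, which is why the
  analysis restricts itself to ≤ 3-syllable words.  When no gesture count is
  annotated, a stand-in of one gesture per consonant, one per nucleus and
  one word-level baseline gesture is used (overridable per word).
  Clusters are counted per onset/coda group; clusters straddling a syllable
  boundary are not merged.
* **FRQ** — lemma frequency from a `(lemma, PoS class)` table.  Lookups are
  PoS-disambiguated (a verb never inherits the counts of a homographic
  pronoun); inflectional sub-entries of the same class are summed at load
  time.  A missing pair yields NaN and the token is excluded from
  correlation analyses — no imputation, since no principled rule exists.

All parameters enter every correlation analysis as `ln(x + 0.001)`; the
offset keeps structural zeros (a vowel-only word's CVR, an epoch-initial
word's ss_ws) finite.  This transform makes such zeros heavy negative
outliers — a property of the method, not a bug of the generator — and the
synthetic forward model is built so injected couplings remain linear down
into that tail (see below).

## Timeline model

Words (ws/we), clauses (cs/ce) and speech-production epochs (ss/se) form a
nesting hierarchy; a speech epoch is a maximal stretch with no pause
≥ 200 ms (the gap comparison carries a 1 ns tolerance so a nominal 200 ms
gap is a pause despite float rounding).  Manual annotations can leave
enclosing tags a few ms inside their words; the correction widens the
enclosing units (`cs := min(cs, ws)` etc.) rather than moving word tags,
because word tags are the most precisely set.  The exact correction used in
the original annotation workflow is not published; this clamp rule is a
reconstruction that guarantees the nesting invariant and non-negative
durations.  Durations are reported in ms (ss_ws, ws_we, we_se, cs_ce,
ss_cs, ce_se).

Covariates: mean acoustic intensity (dB) over [ws, we] from an intensity
trace, and EMG activity as the 60–200 Hz band- and word-averaged relative
spectral magnitude, computed by the same spectral chain as the neural data
(averaged pre-log, then logged; in the pipeline's parameter table the
pre-log value is stored so the shared `ln(x+0.001)` applies uniformly).

## Spectral chain

* CAR over good channels only; bad/seizure-onset channels never enter the
  reference and are dropped.
* Trials span [−2, +3] s around word onset; onsets too close to a recording
  edge are dropped with a warning.
* Multitaper sliding-window FFT: window `round(0.2·fs)` samples (205 at
  1024 Hz, giving the nominal 1024/205 ≈ 5.0 Hz bin spacing), step
  `round(0.02·fs)` samples, 5 discrete prolate spheroidal tapers with
  time-bandwidth NW = 3 (the standard K = 2NW − 1 pairing).  Magnitude
  spectra are the default ("spectral magnitude"); power is a config switch.
  Window timestamps are at window centers, keeping effects temporally
  unbiased.  The alternative 500 ms / 50 ms setting is available in config
  but not default.
* Implementation detail: window DFTs run in single precision, and when the
  frequency cap keeps under ~45 % of the DFT bins the kept bins are
  evaluated directly as per-taper matrix products instead of a full FFT.
  Both paths agree to ~1e-7 relative, far below estimator noise; all
  normalization and statistics run in double precision.
* Baseline correction divides each trial's ASM, per frequency, by its own
  mean over the bins whose centers fall in [−2, −1.8] s, then takes the
  natural log.  By construction the pre-log RSM baseline mean is exactly 1
  (the suite asserts 1e-12).
* The baseline-change test is the two-sided one-sample Wilcoxon signed-rank
  test of log RSM against 0 ("Wilcoxon sign test" is ambiguous; signed-rank
  is the standard choice in this literature, and the exact sign test is
  available as `method="sign"`).  FDR correction is Benjamini–Hochberg,
  applied jointly over channels × frequency × time.

## Neurocorrelation and inference

Pearson r per bin across trials, two-sided p from the t distribution with
n − 2 degrees of freedom; zero-variance bins and trials with missing
parameter values are excluded pairwise.  Bonferroni uses `p < q/m` with m =
all bins × channels.  The threshold ladder descends geometrically from the
5·10⁻⁶ cap ({5e-6, 5e-7, …}); a literal additive descent in steps of 5·10⁻⁶
from 5·10⁻⁶ terminates immediately, so the geometric ladder preserves the
stated intent (monotonically more conservative, capped) where the literal
arithmetic is unusable.  The ladder membership is configurable and recorded
in output metadata.  The reported threshold is the most conservative rung
with at least one significant bin, bounds inclusive.

Residualization: OLS with intercept (always included; standard practice),
per subject, no grouping structure — the original analysis fits per-subject
models over tokens with no random-effects grouping described.  Predictors
are the parameters pairwise-correlated with the target at uncorrected
p < 0.05; rank-deficient predictor sets are pruned in column order with a
log message.  Complete-case analysis throughout; a covariate missing for
all trials is dropped from the model rather than dropping the trials.

The focalized re-analysis restricts frequencies to ≤ 150 Hz and time to
[mean ss − 0.5 s, mean se + 0.5 s] relative to word onset, using per-subject
mean speech bounds so the trial count is identical in every bin.

## Effects

Clusters are 4-connected components of significant bins per channel;
extents are reported at bin centers; the sign is that of the mean r.  Band
labels: alpha 5–10 Hz, beta 15–30 Hz, gamma > 35 Hz, assigned by the
midpoint of the frequency extent (straddling clusters are labeled by
midpoint with a warning — the band rule does not address them).  The
overlap rule compares extents as intervals (edge-to-edge gap, 0 when
overlapping) with inclusive 40 ms / 20 Hz bounds.  Pre/post matching is a
greedy assignment in canonical (channel, time, frequency) order, each pre
effect confirming at most one post effect; the output is invariant to input
ordering.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes; it
is not a model of German speech.

* **Lexicon.** Frequencies `∝ rank^(−s)` (default s = 1), normalized to a
  corpus of 10⁶ tokens.  Syllable count, cluster probabilities and
  non-initial stress all increase with log rank, and per-syllable consonant
  load decreases with syllable count.  These couplings were set once so the
  documented sign structure emerges on the log scale (EoA–FRQ +, EoA–NoS −,
  FRQ–NoS −, CVR–NoS − (weak), NoS–ws_we + (strong)); syllables are
  abstract C*VC* templates and orthography is a random rendering of them.
* **Discourse.** Default token counts {FV 190, NN 120, ADV 110} sit
  mid-range of the per-subject counts typical of this kind of corpus.
  Poisson-sized epochs (mean 6 words), within-epoch gaps uniform in
  [60, 160] ms, pauses uniform in [0.3, 1.2] s; word duration = 0.16 s +
  0.12 s × NoS + N(0, 0.04 s), floored at 80 ms, which makes NoS–ws_we
  strongly positive.  Within an epoch, tokens are ordered by a noisy
  complexity score, so longer and rarer words come later (ss_ws–NoS +,
  ss_ws–FRQ −).  About 5 % of tokens repeat an earlier word to exercise
  deduplication.  Intensity declines with distance from speech start
  (intensity–ss_ws −).
* **Recording.** Per-channel 1/f-shaped noise (spectral shaping of white
  noise, exponent 1, the standard field-potential spectrum).  An injected
  effect multiplies the background's own band component, within the effect
  window around each word onset, by a per-word gain `exp(g + β·z)` (g = 0.5
  mean log-amplitude gain, z the standardized, sign-flipped log parameter).
  Multiplicative gain — rather than additive bursts — is what lets the
  word-wise log RSM track the parameter linearly even for the heavy left
  tail that `ln(x+0.001)` creates at zero-valued parameters (a purely
  additive burst cannot push band power below background).  β is calibrated
  iteratively: each pass measures the realized slope and residual noise of
  the band- and window-averaged log RSM on the composite signal — noise that
  includes both estimator variance and the contamination of one word's
  [−2, −1.8] s baseline by its neighbors' modulation in continuous speech —
  and rescales β to the slope the target Pearson r requires (up to 4 passes,
  stopping within 0.015 of the target).  The target r is defined on the
  band/window-averaged response; per-bin correlations are attenuated by
  per-bin estimator noise, as in real data.

What the generator does **not** emulate: real phonology and coarticulation,
non-stationary background spectra, artifacts, volume conduction between
channels, EMG physiology, or intelligible audio.  Passing tests therefore
demonstrate that the analysis machinery is correct and calibrated under its
own assumptions — not that those assumptions hold in any particular
recording.

## Validation runs and problem sizes

The acceptance-style suite runs, per condition: effect recovery at 50 seeds
(200 trials, 16 channels, CVR-coupled 70–110 Hz effect at target r = 0.5),
confound removal at 20 seeds (200 trials, 8 channels, NoS-coupled effect at
r = 0.6 with an EoA covariate constructed at r ≈ −0.75 to NoS — the
two-parameter table isolates the collinearity mechanism under test), sign
structure at 20 generator seeds, 100 parameter permutations and 200
symmetric-null replicates for calibration.  `scripts/acceptance.py` uses 20
recovery and 10 confound seeds, sizes chosen as a practical single-CPU run;
rates are reported with their n.

## Known limitations

* The EoA surrogate's weights are conventions, not estimates; only signs
  and monotonicity are meaningful.
* The calibration targets the band-averaged coupling; the realized r for
  parameters with extremely skewed distributions can undershoot by a few
  hundredths in dense speech.
* The ladder's exact membership is a convention (geometric descent); any
  strictly decreasing sequence capped at 5·10⁻⁶ can be configured.
* The per-bin correlation p-values come from the t distribution.  At
  moderate thresholds they are well calibrated (the permutation null
  reproduces α almost exactly), but in the extreme tail used by Bonferroni
  (~4·10⁻⁷) the non-normality of log RSM — especially the low-variance,
  negatively inter-correlated baseline bins — makes them mildly
  anti-conservative: across recovery runs, the fraction of runs with at
  least one corrected false positive on a null channel is roughly 0.08–0.12
  rather than the nominal 0.05.  Rank- or permutation-based bin tests would
  remove this at substantial cost; the parametric test is what the method
  specifies.
* Clause structure in the generator is minimal (epochs split at most once),
  so cs_ce/ss_cs/ce_se carry little independent variance.
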