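# Methods

## Pipeline

Samples are tasks. For each task the EEG contributes one analysis window
(default the full 40 s task period) and the fNIRS a set of short windows
whose starts are feature columns, not extra samples. The processing order
replicates the classical single-dataset workflow: extract features over
the whole cohort, rank by one-way ANOVA across the three workload levels,
min–max normalise to [−1, 1] within each participant, then stratified
5-fold SVM cross-validation per workload pair. Ranking on the full sample
set before cross-validation is an information leak — selected features
have seen the test folds — and measurably inflates absolute accuracies on
small cohorts. It is kept because it is the order this analysis family
uses in practice; a fold-nested alternative is available by placing
`AnovaTopKSelector` inside an sklearn `Pipeline` within the CV loop.
Comparisons between task pairs remain meaningful because all pairs share
the same inflation.

## Estimators and numerical choices

* **Filtering.** Butterworth order 3, zero-phase. Initial conditions use
  Gustafsson's method, which makes forward–backward filtering exactly
  symmetric under time reversal; the cost is a short edge transient on
  signals with strong out-of-band content (e.g. a DC step), which the
  windowing upstream of every estimator keeps out of the statistics.
  The EEG prefilter is 1–45 Hz; analysis bands are delta 0.5–4 Hz
  (truncated below 1 Hz by the prefilter, both applied as specified),
  theta 4–7 Hz, alpha 8–15 Hz. fNIRS is low-passed at 0.04 Hz when raw;
  the 0 Hz lower edge of that band is vacuous and dropped.
* **Spectra.** Welch with periodic Hann windows, per-frame constant
  detrend, 50% overlap; band power integrates the PSD over the band by
  trapezoid. MSC uses 8 Welch segments by default (single-segment
  coherence is identically 1 and is rejected) and reduces to the mean
  over in-band frequency bins.
* **MI.** Equal-width histogram over each series' own range,
  ⌈√N⌉ bins capped at 32, log base 2, 0·log 0 ≡ 0. The plug-in estimate
  is biased upward for continuous data at finite N; the bias is common to
  both classes being compared, so it does not generate spurious contrast.
* **PLV.** Phases from the analytic signal after band filtering; 10% of
  samples trimmed from each edge against Hilbert end effects; windows
  shorter than 3 cycles of the band's lower edge are rejected.
* **Band handling.** MI, PCC and PLV operate on band-filtered series so
  that "per-band" features are well defined for time-domain estimators;
  MSC averages coherence bins of the raw segment. This is configurable
  but is the default reading.
* **Connectivity matrices** are computed by vectorised paths (one Hilbert
  / FFT / discretisation per channel, then all pairs) and explicitly
  symmetrised; the scalar pairwise functions define the semantics and the
  tests pin the two routes together. Diagonals: 1 for PCC/MSC/PLV, the
  marginal entropy H(x) for MI.
* **ANOVA.** Hand-vectorised between/within sum-of-squares ratio with
  p from F(g−1, n−g). Zero within-group variance with unequal means maps
  to (F = ∞, p = 0); all-constant columns have undefined F and rank last.
  Ties break by larger F, then lower column index. Raw p-values, no
  multiple-testing correction (the screen is a ranking, not a test).
* **mBLL.** The 2×2 extinction system is solved per channel and sample;
  default coefficients are standard published 760/850 nm values with
  DPF 6 and 3 cm separation, all overridable.
* **Classification.** SVC(C = 1, RBF, γ = 'scale'); KNN (k = 5),
  depth-5 tree and LDA are included as comparators only. Folds are
  stratified with seeded shuffling; a subject-wise mode
  (`StratifiedGroupKFold`) is available because sample-wise folds let a
  participant appear on both sides of a split. The reported accuracy is
  the mean of fold accuracies; ROC/AUC come from pooled decision scores
  with ties stepped simultaneously.
* **Topographic maps** use inverse-distance weighting (power 2) on the
  2-D montage, masked to the sensors' convex hull. IDW weights are
  convex, so the interpolant is bounded by the data and exact at sensor
  positions. The montage is a schematic 10-20 projection, adequate for
  localisation figures, not a forward model.

## Synthetic cohort generator

The generator emulates the block structure of a three-level n-back study:
each session is a 5 s lead-in rest followed by `n_sets` series of three
63 s task blocks (2 s instruction, 40 s task of nominally 20 trials, 1 s
stop, 20 s rest), one block per workload level in seeded random order.
The default cohort (26 participants × 3 sessions × 3 sets) therefore has
702 tasks. Trials inside the 40 s task are not modelled individually;
all planted effects are stationary at the task level, which is the
granularity the window-based features operate at.

EEG channels are 1/f (pink) background noise (σ = `noise_sd` = 1) plus
sinusoidal oscillators at 2, 6 and 10 Hz (amplitudes 1.0 / 0.8 / 1.0)
present during task periods, with random phase per task and a lognormal
amplitude envelope (σ = 0.35) redrawn every 5 s. The envelope timescale
matters: band-power variability then decreases with window length, so
longer EEG windows genuinely help — the mechanism behind the window-size
analysis. Planted effects, all linear in load rank (0/2/3-back → 0/1/2):

* posterior channels (POz, O1, O2) carry a stronger alpha oscillator
  (amplitude 2.0) suppressed by 15% per rank;
* frontal pairs (Fp1–Fp2, Fp1–AFz) share a common 6 Hz source mixed in
  with weight 0.4 × rank, raising theta-band coupling with load;
* fNIRS channel AF8 scales its task response by (1 + 0.5 × rank).

These magnitudes were fixed once at design time as physiologically
plausible values strong enough to be recoverable at reduced cohort scale
without saturating the hard (2-back vs 3-back) contrast.

The hemodynamic model convolves a unit-area double-gamma HRF (peak shape
6, undershoot shape 16, ratio 1/6, peak at 6 s) with a task boxcar whose
neural drive adapts exponentially (τ = 12 s, habituation), on top of
random-walk drift (step σ = 0.02) and white noise (σ = 0.3), with
lognormal per-task amplitude jitter (σ = 0.3). HbR is an anticorrelated
copy of HbO (−κ·HbO, κ = 0.5) plus independent noise. The adaptation and
drift are what make short windows near the response peak more informative
than 40 s windows — long windows dilute the transient and accumulate
drift — mirroring the qualitative window-size finding the pipeline is
meant to reproduce.

All randomness derives from a single seed; per-(participant, session)
streams are keyed by index so any subset of the cohort is bit-reproducible
in isolation.

**What the generator does not emulate:** volume conduction (planted
coupling is a genuinely shared source, so connectivity estimators see a
cleaner signal than scalp EEG provides), ocular/muscle artifacts, ERP
morphology within trials, optode geometry, or between-participant effect
heterogeneity beyond noise. Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration, not expected accuracy on real
recordings; absolute accuracies on synthetic cohorts are not comparable
to published dataset results.

## Validation studies and problem sizes

`neurofuse.experiments` runs four studies, used by both the test suite
and `scripts/acceptance.py`. They use deliberately reduced problem sizes
chosen to keep a full run in the minutes range on one core:

* *Feature accounting* — one session at the 28-channel EEG / 36-channel
  fNIRS configuration (an 8 s EEG window suffices; column counts do not
  depend on window length) plus the default cohort's event table.
* *Null calibration* — 8 participants × 1 session, 12 EEG + 8 fNIRS
  channels, all effects zero: ~10³ feature columns for the ANOVA
  false-positive rate (averaged over 3 seeds), and 50 label permutations
  of the fixed top-10 set for the chance-level CV check. Labels are
  permuted with the feature set held fixed; re-running selection inside
  the permutation would measure the selection leak instead of the
  classifier's null.
* *Effect recovery* — 10 seeded cohorts of 8 participants, 20 s EEG
  windows: ANOVA top-10 hit rate, hybrid pair accuracies, per-channel
  accuracy-map peaks.
* *Window-size study* — 5 seeded cohorts of 6 participants, sizes
  {5, 10, 20, 40} s; fNIRS scored at the best window position per size
  (coarse 2 s grid), mirroring the position-optimisation step, EEG
  anchored at task onset with PSD features.

## Known limitations

Trial-level responses, artifact removal (the ocular stage is a
pass-through hook), channel-quality rejection and short-separation
regression are out of scope. The full-sample selection default leaks
test-fold information, as discussed above. MI/PLV/MSC defaults (bins,
trim fraction, segment count) are sensible but not optimised per dataset.
The window coordinate for position sweeps is defined
relative to each task block's onset; other conventions require passing an
explicit offset.
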