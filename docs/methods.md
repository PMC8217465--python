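# Methods

`hfoloc` implements an automated detector of high-frequency oscillations
(HFOs) in intracranial EEG, a coverage rule that turns per-channel HFO rates
into a putative epileptogenic zone (EZ), and the cohort-level statistics
used to relate marked regions to surgical outcome. Because clinical iEEG
recordings of this kind are not publicly deposited, the package includes a
first-class synthetic-data generator with a complete ground-truth ledger;
every stage is validated against that ledger and against brute-force
statistical oracles.

## Signal model and segment selection

Recordings are channel × time matrices in microvolts at a nominal
4,096 Hz. Analysis operates on a bipolar montage of adjacent contacts on
the same depth-electrode shaft (`<shaft>i − <shaft>(i+1)`, low contact
minus high; the sign convention is stated because it differs across labs).

The analyzed data are 5 minutes of interictal slow-wave sleep. Sleep is
identified from the iEEG itself: a 30-s epoch qualifies when delta-band
power (0.5–4 Hz) exceeds 25% of broadband power (0.5–45 Hz), both computed
by Welch periodogram, and the earliest run of ten consecutive qualifying
epochs is selected. The per-epoch statistic is the median across channels —
the qualifying rule could equally be per-channel or mean-based; the median
was chosen as the most outlier-resistant single-number summary. An optional
exclusion-interval argument removes epochs near annotated seizures; with no
annotations it is a no-op.

## Detection pipeline

Per channel and per band (ripples 80–200 Hz, fast ripples 200–500 Hz):

1. **Zero-phase bandpass.** A symmetric (linear-phase) FIR designed with a
   Hamming window; transition width 25% of the lower band edge, clipped to
   [15, 60] Hz (677 taps for the ripple band at 4,096 Hz). The kernel is
   applied once by FFT convolution with the group delay compensated
   exactly, so the net phase shift is zero at every frequency. This is
   algebraically equivalent to forward–backward filtering for a symmetric
   kernel, at half the cost and with a single-pass magnitude response.

2. **Peak extraction.** All strict local maxima of the absolute filtered
   signal; plateaus take their first sample. Eight absolute peaks span four
   oscillation cycles — the conventional minimum for an HFO.

3. **PPDC baseline.** Within each contiguous 5-s window, peak amplitudes
   are sorted ascending (the peak point distribution curve). The turning
   point is the index of maximum perpendicular distance from the curve to
   the chord joining its endpoints (parameter-free knee detection); all
   peaks before it are baseline points, and the window's baseline mean and
   SD are computed over them. Degenerate cases: a flat curve has no knee
   and the last index is used (every peak is baseline); a zero baseline SD
   is replaced by 5% of the baseline mean so thresholds remain finite and
   scale-covariant. Windows with fewer than 20 peaks fall back to the
   whole-channel PPDC. A sliding (1-s hop) window variant is available by
   configuration; the default is contiguous windows with thresholds
   constant within a window.

4. **Thresholding.** A candidate is a maximal run of ≥ 8 consecutive peaks
   above mean + 3 SD that contains ≥ 6 consecutive peaks above
   mean + 10 SD (ripples) or mean + 9.5 SD (fast ripples). Each peak's
   3-SD condition uses its own window's baseline; the high threshold for a
   run uses the window containing the run's first peak (the run cannot be
   delimited before per-peak thresholds exist, so this is the operational
   reading of "thresholds from the run's window"). The 6-peak run must lie
   inside the 8-peak run. Candidates separated by less than 10 ms are
   merged. Event start/end are the first/last peak of the run; the event
   also carries an amplitude-weighted center time, which is the quantity
   to use as the event midpoint — span endpoints are quantized at the
   half-period spacing of absolute peaks (~5 ms at 90 Hz), while the
   weighted center is insensitive to which marginal edge peak clears the
   threshold and still exposes any filter group delay.

5. **Gibbs-ringing rejection.** Sharp non-oscillatory transients (epileptic
   spikes) ring when bandpassed, producing false in-band oscillations. The
   discriminator works on the *raw* segment around the candidate (± 50 ms
   margins, widened to at least fs/10 samples): compute its periodogram,
   smooth by a ± 10 Hz moving average, find the in-band power maximum f\*,
   and form delta = P(f\*) − P(f\* − offset) with offset = half the band
   width (≥ 30 Hz). A genuine oscillation concentrates power at its own
   frequency, giving delta > 0; spike ringing rides on a monotone-decreasing
   spectrum, giving delta ≤ 0, and the candidate is discarded. For the
   narrowband signals at issue, band power equals the squared radius of a
   two-dimensional time-delay embedding, so this spectral form is the
   practical equivalent of a phase-space power comparison.

Thresholds are relative to the per-window baseline, so detection is
invariant to rescaling a channel; raising any SD multiplier can only remove
events.

## EZ delineation

Retained events are counted per channel. Fast ripples are the primary
marker; if none was retained anywhere, ripple counts are used and the
fallback is recorded. Channels are ranked in descending rate (stable sort;
ties keep input order) and the EZ is the minimal top-ranked prefix whose
cumulative event count reaches 72% of all events; zero-event channels are
never included. An alternative reading — the top 72% of event-positive
channels — is available behind a configuration switch (`rule="channels"`);
with a single fixed-duration segment, rates and counts rank identically.

## Clinical statistics

* **RatioChann(ev)** = (#ChannRem − #ChannNonRem) / (#ChannRem +
  #ChannNonRem) over channels marked by method *ev*; bounded in [−1, 1],
  antisymmetric under swapping the counts, undefined when no channel is
  marked.
* **Outcome**: Engel class I = good (seizure-free); II and III = poor.
* **Sensitivity/specificity** use region-level bookkeeping: for
  good-outcome patients each marked-and-removed region is a true positive,
  each marked-but-unremoved region a false positive, and the unmarked
  remainder one true-negative token per patient; for poor-outcome patients
  marked-and-removed regions are true positives and the residual EZ one
  false-negative token per patient, and patients with unremoved marked
  regions are excluded because those marks cannot be adjudicated. What
  counts as one "region" is a convention, so these rates are reported but
  not treated as reference values. Specificity is the standard
  TN/(TN+FP).
* **Fisher's exact test** is two-sided by the probability method (sum of
  margin-preserving tables with probability ≤ the observed table's),
  delegated to `scipy.stats.fisher_exact` and cross-checked in the tests
  against a direct hypergeometric enumeration.
* **Wilcoxon rank-sum** is exact for n₁+n₂ ≤ 20: a dynamic program over
  the doubled midranks counts assignments whose rank sum deviates from its
  mean at least as much as observed (the permutation distribution is
  symmetric, with or without ties); larger samples use the tie-corrected
  normal approximation. The exact threshold keeps cohort-scale comparisons
  (5 vs 9 patients) exact.
* **Consistency** between two marking modalities: a patient is evaluable
  when both region sets are present (`/` rows excluded; `Normal` is an
  evaluable empty set); at-least-one = non-empty intersection under exact
  label matching, complete = set equality. Exact matching is the only
  reproducible criterion for printed labels; it cannot encode anatomical
  containment (e.g. an amygdala label inside a resected temporal lobe), so
  pairs whose printed agreement relied on anatomical adjacency are not used
  as reference values.

The packaged cohort fixture carries the 15-patient clinical table; the
association panels (complete removal vs outcome, including the multimodal
criterion "electrodes covered all imaging-suspicious areas AND HFO-marked
areas completely removed") are shipped as stored 2×2 counts because the
electrode-coverage flags are not derivable from printed label sets.

## Synthetic data

The generator emulates exactly what the detector must separate:

* **Background**: Gaussian 1/f^α noise (α = 1 by default, the standard EEG
  approximation) via spectral shaping, each channel normalized to the
  requested SD (default 20 µV) and driven by its own spawned substream of
  one master seed.
* **Bursts**: Hann-tapered sinusoids, frequency inside the target band,
  ≥ 4 cycles for detectable events, amplitude expressed in multiples of the
  local background SD so the 3/10/9.5 SD thresholds map directly onto
  ground truth.
* **Spike transients**: Gaussian-envelope monophasic deflections ≤ 80 ms —
  no oscillatory component, monotone-decreasing in-band spectrum, but
  strong filter ringing: the false-positive generator.
* **Cohorts**: per-patient region sets for three modalities, removal sets,
  channel counts and Engel outcomes, with complete removal drawn
  conditionally on outcome so the association tests have a known signal.

The standard benchmark recording is 10 channels × 5 min at 4,096 Hz with
40 ripples, 20 fast ripples (both at 10–15× background SD) and 30 spikes;
spike-only robustness uses 100 seeded single-channel 10-s recordings with
8 spikes each. On these conditions the detector reaches recall 1.0 and
precision ≥ 0.95 with zero spike-induced retentions; the few "false"
positives are double detections of one burst across band edges, not noise.

What the generator does not model: ictal activity, realistic sleep
architecture beyond delta-band power, inter-channel correlation, electrode
artifacts, or line noise. Passing on synthetic data therefore demonstrates
correctness of the algorithmic contract — not clinical performance on real
recordings, where background nonstationarity and artifact diversity are
harsher.

## I/O and numerical conventions

EDF reading goes through `mne`; EDF writing is a small built-in 16-bit
writer (one 1-s record per second, per-channel physical scaling, microvolt
dimension) verified round-trip against `mne`'s reader to within one
quantization step. A self-describing delimited-text format (header row of
labels, `# sample_rate_hz=` comment) is the text fallback. Times are
seconds from recording start; all intervals are half-open; events belong to
the 5-s window containing their first peak.

## Known limitations

* The turning-point and phase-space-discriminator algorithms of the
  original detector are published only as prior-work citations; the knee
  detection and spectral-offset discriminator here are documented
  stand-ins with the stated rationale, and both are isolated behind small
  functions so alternatives can be substituted.
* Whether baseline SD should be per-window or per-channel is not settled;
  per-window is the default, whole-channel enters only via the sparse-window
  fallback.
* Region-level confusion counting and anatomical overlap between printed
  region labels are conventions; numbers that depend on them are clearly
  separated from label-exact quantities.
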