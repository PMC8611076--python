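# Methods

`devconn` re-implements, as a tested library, the signal-analysis and
statistics chain used to study directed communication in the developing
entorhinal (LEC) – hippocampal (HP) – prefrontal (PFC) network: detection of
discontinuous oscillatory events in neonatal LFP, event-based spectral
power, magnitude and imaginary coherence, MVAR-based generalized partial
directed coherence (gPDC), optogenetic evoked-response quantification, and
the behavioral/statistical scoring.  Because the scientific claims of such a
chain depend on estimator behavior that is hard to audit on real data, the
package is organized around a synthetic-data generator with exact ground
truth: every analysis stage has a recovery test against quantities that are
known by construction.

## The synthetic model

### Latent dynamics

Three regions are modeled as a vector autoregressive (MVAR) process at
100 Hz.  Each region's own dynamics are the cascade of two damped
resonators, one in theta (8 Hz, pole radius 0.80) and one in beta (20 Hz,
radius 0.55), giving the broad theta–beta spectral hump characteristic of
neonatal spindle bursts.  Directed interactions enter as lag-one
cross-coefficients with gains

    g(LEC→HP) = 0.35,  g(HP→PFC) = 0.25,  g(LEC→PFC) = 0.08,

reproducing the qualitative hierarchy of the biological circuit (strong
entorhinal drive to hippocampus, moderate hippocampo-prefrontal drive, weak
direct entorhino-prefrontal drive).  The generating model — coefficient
matrices and innovation covariance — is returned alongside the data, so the
closed-form gPDC of the truth is always available.  Stability is checked via
the companion-matrix spectral radius; unstable configurations are rejected.

The "GE" group (the dual-hit genetic–environmental risk condition) modifies
three parameters relative to control: the LEC→HP gain is multiplied by 0.4,
burst power by 0.5, and the fraction of light-responsive units by 0.4.

### Bursts, background, and geometry

The latent process is upsampled to 1 kHz (polyphase, band-limited) and gated
by a burst envelope: burst onsets follow a renewal process whose gap rate is
compensated for the busy period so the realized rate matches the configured
events/min (default 6); durations are log-normal with mean 3 s (truncated at
1.5 s so every true event clears the detector's 1 s floor with margin);
edges are 100 ms raised cosines; outside bursts the oscillatory component is
attenuated to 5 % amplitude (−26 dB power).  To this are added, per region,
1/f background noise (spectrally shaped Gaussian, exponent 1.0, 25 µV SD)
and a continuous 2–4 Hz slow rhythm at half the noise SD — prominent, as in
neonatal cortex, but mostly below the 3–100 Hz detection band.

Burst amplitude is set by a signal-to-noise target: the variance of the
oscillatory component inside bursts, band-passed to the 3–100 Hz detection
band, is `10^(SNR/10)` times the background variance in the same band
(default 6 dB).  This band-referenced definition is what makes the detector
benchmarks meaningful; because the burst spectrum is concentrated near
theta, the implied in-event over baseline PSD ratio at 8 Hz is much larger
(≈ 15–20, i.e. > 10 dB at the peak) — the property tests assert exactly
these construction-implied values.

Optionally an instantaneous mixing matrix is applied across regions (to
emulate volume conduction) and each region can be expanded into a laminar
probe: channel weights follow a sink/source dipole (Gaussian spread, source
two sites above the sink), which gives the current-source-density analysis a
known sink location.

### Spikes and behavior

Spike trains are inhomogeneous Poisson processes whose rate is modulated by
the instantaneous 4–30 Hz amplitude of the region's LFP (baseline 2 Hz,
modulation depth 0.8).  Responder units emit one extra spike with
probability `p_resp` at a uniform 3–10 ms latency after each light pulse.
Behavior tables draw per-animal object-interaction times from truncated
normals whose group means equal the published control/GE means, and include
a 10 % fraction of low-exploration animals so the < 20 cm/min exclusion rule
is exercised.

What the generator does **not** emulate: non-stationary background (state
changes, movement artifacts), spike waveforms and sorting errors,
conduction delays beyond MVAR lags, within-burst frequency drift, and
electrode drift.  Passing recovery tests therefore demonstrates estimator
correctness under the model's assumptions, not robustness to every
real-data pathology.

## Analysis chain

**Filtering** is zero-phase throughout (Butterworth run forward–backward via
`sosfiltfilt`), which doubles the effective order; this is documented rather
than compensated.  LFP extraction low-passes at 1500 Hz (third order) and
resamples to 1 kHz; since 1500 Hz exceeds the post-resampling Nyquist
frequency, an additional 400 Hz anti-alias stage is applied by default and
can be disabled to mirror the minimal published recipe exactly.

**Event detection** band-passes to 3–100 Hz, computes a sliding RMS
envelope (200 ms window, 10 ms step), histograms the RMS values (100 bins
from 0 to the maximum) and fits a Gaussian to the bins up to the histogram
mode — the body of the non-oscillatory background.  The threshold is
`mu + k*sigma` with `k = 2.5` by default, chosen so that long stretches of
pure noise produce zero events.  The fit is bounded (center at most the
mode, width at most the mode value) because a one-sided fit is otherwise
under-determined; on failure a robust `median + k·1.4826·MAD` fallback is
used with a warning.  Supra-threshold intervals are merged across gaps
< 200 ms, shrunk by half an RMS window per side to undo envelope smearing,
and kept only if longer than 1 s.  Raising `k` monotonically shrinks the
total detected time, but can *split* merged events, so the event count is
not monotone — a property worth knowing when comparing thresholds.  The
"mode" of the histogram is interpreted as the modal bin; fitting up to the
maximal RMS value instead is available via `fit_to="max_value"`.

**MUA detection** thresholds the 500–5000 Hz band at −5 SD (plain SD by
default, MAD-based optional), takes the minimum of each sub-threshold
excursion and enforces a 1 ms dead time.  The false-positive rate of this
scheme on Gaussian noise follows the Rice level-crossing formula, which the
tests use as an independent oracle at a lower threshold where the expected
count is large enough to compare.

**Spectra.** Event-based PSDs tile each event into non-overlapping 1 s
segments and average Hamming-tapered periodograms (Welch, 1 Hz resolution);
remainders shorter than 1 s are discarded.  Baseline power P0(f) uses the
same estimator on inter-event gaps (warning below 10 segments); relative
power is P/P0.  Continuous recordings are tiled whole-trace.  Band averages
are arithmetic means over grid points inclusive of both edges.
Time–frequency maps use the complex Morlet wavelet with center-frequency
parameter 6.

**Coherence.**  Cross- and auto-spectra are averaged over co-occurring 1 s
epochs — stretches where the event intervals of both channels intersect for
at least a second.  Magnitude coherence follows the cross-spectrum
normalized by the two auto-spectra; the imaginary coherency's magnitude is
reported alongside, since it is immune to instantaneous (volume-conducted)
mixing.  The surrogate floor re-pairs epochs by random derangements and
averages the recomputed coherence.

**gPDC.**  Epochs are band-limited (default 1–45 Hz, zero-phase) and
decimated to 100 Hz, an MVAR model is fit by pooled least squares without
crossing epoch boundaries (order by BIC up to 20, or fixed), stability is
enforced, and the generalized partial directed coherence

    gPDC_{i←j}(f) = (|Ā_ij(f)|/σ_i) / sqrt(Σ_k |Ā_kj(f)|²/σ_k²),
    Ā(f) = I − Σ_r A_r e^{−2πifr/fs}

is band-averaged (default 4–30 Hz) per ordered region pair.  The
column-normalization identity Σ_i gPDC² = 1 holds by construction and is
asserted on every call.  The published chain de-noised with an unspecified
wavelet routine before gPDC; a configurable band-pass replaces it here
because it is transparent and reproducible.  One channel per region enters
the model (in real data: the CA1 pyramidal-layer channel and the LEC site
700 µm above it, chosen upstream).

**Evoked responses.**  Firing probability counts spikes (not pulses) in the
20 ms window after each pulse onset divided by the pulse count; the PSTH
uses the same normalization so its bins over [0, 20) ms sum exactly to the
firing probability.  The modulation index (r_during − r_pre)/(r_during +
r_pre) is classified by a paired permutation test (sign flips of per-sweep
rate differences, 1000 permutations, two-sided α = 0.05, +1-corrected
p-values); with fewer than five sweeps the class is undefined.  Evoked LFP
amplitude is the unsigned extremum of the baseline-subtracted
stimulus-locked average within 100 ms (baseline: 50 ms pre-pulse).  CSD is
the negative second spatial difference with Vaknin end-padding and optional
three-point Hamming smoothing; note the padded edge channels are not zero
even for a linear depth profile — only interior channels obey the
second-difference identity.  Ramp/train power and coherence changes compare
the 1.5 s before onset with the last 1.5 s of stimulation (or the 1.5 s
after offset for presynaptic-silencing experiments); power (or Welch
segments) is pooled across sweeps *before* the ratio, because averaging
per-sweep ratios with few-segment denominators is biased upward (Jensen).
"Normalized" changes are reported as ratio − 1; a difference variant gives
identical sign conclusions.  eEPSC features come from the average of ≥ 2
voltage-clamp sweeps: peak amplitude (baseline-subtracted inward magnitude),
onset as the first post-stimulus time the smoothed response speed exceeds
10 pA/ms, 20–80 % rise time, CV as SD/mean of per-sweep peaks, and a
responsiveness call requiring > 3 baseline SDs within a < 9 ms onset.

**Statistics.**  The rank-sum test reports the rank sum of the first
sample, a tie- and continuity-corrected normal z, and an exact p when
min(n) ≤ 10 without ties.  The chi-square test for two proportions applies
the Yates continuity correction by default — this is the convention under
which the published chi values (9.45, 5.43) follow from the published
counts; the uncorrected variant (11.1, 6.4 on those counts) is available.
The published normality screen ("Levene's test (F-test)") is mirrored as a
variance-homogeneity gate that selects ANOVA versus rank-sum; using a
variance test to screen for normality is unconventional and is flagged as
such.  The discrimination index is (novel − familiar)/(novel + familiar);
animals moving < 20 cm/min (strictly) are excluded before scoring.  No
multiple-testing correction is applied, matching the source conventions.

## Numerical choices and degenerate inputs

* Times are float64 seconds, epochs half-open `[start, stop)`; channel
  indices 0-based internally.
* HDF5 containers store the signal as float64 so write→read is exact.
* Constant signals: event detection warns and returns no events; MUA
  detection warns and returns empty trains; `rms_threshold` raises on a
  degenerate envelope.
* MI with r_pre = r_during = 0 is defined as 0.
* Coherence magnitudes are clipped at 1 to absorb rounding; `imC ≤ C ≤ 1`
  is validated on every spectrum.
* MVAR fits require 10·k²·p pooled samples and reject unstable solutions.
* Derangement sampling retries until no fixed point remains (expected ≈ e/(e−1)
  draws).

## Problem sizes used in validation

Recovery and calibration runs use 120 s simulations for gPDC direction and
group-contrast checks (50 seeds each), 600 s for detector precision/recall
and the pure-noise floor, 60 s at 100 Hz for MVAR coefficient recovery,
1200 pulses for firing-probability recovery, and 5000 replicates for
type-I-error calibration of the rank-sum and permutation tests.  These
sizes put the Monte-Carlo error of each check well below the tolerance it
is compared against.

## Known limitations

* The laminar model is a fixed dipole, not a multi-source volume conductor;
  CSD tests validate localization, not amplitude calibration.
* The MVAR generator has no moving-average component; BIC order selection
  on real data with mixed dynamics will behave less crisply than in the
  recovery tests.
* The epoch-based coherence estimator is biased upward at small epoch
  counts (~1/√n); the derangement surrogate quantifies, but does not
  remove, this floor.
* Group-level numbers from the underlying study that depend on its raw
  recordings (means ± sem of power, coherence, firing rates) are not
  reproducible without those recordings; the package validates the
  estimators, the exact count-based statistics, and the direction and sign
  structure of the group contrasts.
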