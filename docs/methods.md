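# Methods

This note documents the models behind `lumispark`: what the synthetic movie
generator simulates, the analysis conventions, the defaults and why, and what
the simulations do and do not show about real recordings.

## Event schedules

Spontaneous contractions are modelled as a homogeneous Poisson process
thinned by a refractory dead time (an arrival inside the window of the last
accepted event is discarded, not delayed). The `rate` argument is the
*realized* mean event rate after thinning: the underlying intensity is
compensated as λ = r / (1 − r·τ), which makes the non-paralyzable dead-time
rate λ/(1 + λ·τ) equal r exactly. Scenario rates therefore read directly as
observed event frequencies — 0.2 Hz for short recordings in the second
signalling period, 0.02 Hz for hours-long recordings, ×1.5 under the
mitochondrial-uncoupler and uniporter-inhibitor presets, zero under
anaesthetic block. The default refractory period is 3.0 s, chosen so that a
luminescence transient's suprathreshold span (including its rostro-caudal
wave spread) can never bridge two consecutive events; note this caps the
realizable rate at 1/τ ≈ 0.33 Hz. Event peak amplitudes are log-normal
(mean 1.0 µM free Ca²⁺, log-SD 0.25) on a 0.05 µM resting baseline.

The hours-long scenario places activity inside two developmental windows
(17.5–19.5 hpf and after 23 hpf) separated by a quiet gap, matching the two
signalling periods of trunk muscle development.

## Ca²⁺ waveforms

Each event contributes a difference-of-exponentials pulse normalized so its
peak equals the scheduled amplitude; overlapping events superpose.
Defaults: cytosol (rise τ 0.3 s, decay τ 0.6 s; Ca²⁺-level rise 10–90%
≈ 0.24 s, decay 90–10% ≈ 1.6 s — a transient that rises sharply and decays
within 1–2 s, and whose rise is resolvable at 11.9 Hz while only slightly
overestimated at 4.7 Hz); mitochondrial matrix (rise τ 0.144 s, decay
τ 2.5 s). The mitochondrial decay is deliberately slower — matrix clearance
lags sarcoplasmic re-uptake — while its rise constant is back-solved so both
compartments share the same 10–90% upstroke *at the luminescence level*:
with a difference-of-exponentials pulse, slowing the decay alone also
reshapes the (peak-normalized) upstroke, and the back-solve keeps "rise
parameters indistinguishable, decay clearly longer" a property of the
ground truth rather than an artifact.

Waves propagate rostro-caudally: somite s is delayed by distance/speed
(default 1.6 mm/s) and attenuated by (1 − decrement)^distance with a default
decrement of 0.15 per mm. An optional rise-slowing term increases the rise
constant per mm towards the tail.

## Indicator photophysics

Aequorin luminescence follows a Hill law R = pool·k·Ca^h/(K^h + Ca^h) with
cooperativity h = 2.5 and half-saturation K = 10 µM, placing the whole
physiological range (0.05–2 µM) in the power-law regime where the log-log
slope equals h. The rate constant default (k = 0.0032 s⁻¹ at saturation,
pool 10⁶ photons/pixel) gives ≈ 5.7 photons s⁻¹ pixel⁻¹ at a 1 µM event
peak — a genuinely photon-limited regime in which single frames at 30 Hz
carry well under one photon per pixel for dim events. Consumption depletes
the pool by the emitted photons, with per-step emission capped by the
remaining pool, so cumulative output can never exceed pool × yield.

The ratiometric indicator responds as ratio = r_min + (r_max − r_min)·θ with
θ = Ca^n/(Kd^n + Ca^n), Hill slope n = 1.04. Its apparent Kd is not
specified by any measurement we reproduce; the default of 3.0 µM is a
low-micromolar affinity appropriate for µM-scale muscle transients and is
configurable.

Both indicators respond effectively instantaneously to rising Ca²⁺ and
release with first-order kinetics (rate ln 2/t½) when Ca²⁺ falls — a
one-sided follower rather than a symmetric low-pass. A symmetric filter at
these off half-times (0.4 s aequorin, 0.5 s ratio) would stretch the rising
phase to ~1.9 s and contradict the sharp observed upstrokes; physically,
photoprotein consumption and FRET responses track Ca²⁺ binding quickly while
unbinding is rate-limited. The aequorin off half-time default sits at the
fast end of its literature range (0.4–0.8 s) because the 2.5-power law
compresses Ca²⁺ decay 2.5-fold in the luminescence signal: a slower release
would floor cytosolic and mitochondrial luminescence decays at the same
value and mask the compartment difference the decay statistics must resolve.

Channel photobleaching under continuous excitation is mono-exponential per
channel. The default time constants are back-solved so 15 minutes of
illumination removes exactly 9% of the donor (τ ≈ 9543 s) and 19% of the
acceptor (τ ≈ 4271 s); because the acceptor bleaches faster, the
FRET/donor ratio of an event-free movie drifts downward.

## Rendering and the camera

Expected photon rates per binned pixel are: the somite's indicator emission,
plus a uniform substrate glow over the embryo (default 0.02 photons s⁻¹ px⁻¹,
the spontaneous coelenterazine emission that the EB term estimates), plus a
dark rate everywhere (0.02 s⁻¹). Counts are Poisson in (rate × integration
time), scaled by gain, with additive Gaussian read noise (default SD 0.1,
sub-photon as appropriate for a photon-counting EM-CCD), clipped to
[0, 65535]. Frame i spans [i·Δt, (i+1)·Δt); the luminescence path
supersamples the photophysics ×4 and averages within each span so frame
values integrate the emission over the span — this preserves sub-frame wave
timing that midpoint sampling would quantize. One top-level seed drives all
randomness; renderers are bit-reproducible given seed and configuration.

Split-field FRET movies place the donor in the left half-field and the
acceptor in the right, with an optional integer channel offset emulating
image-splitter misalignment. Both channels share a common multiplicative
motion factor during events (cancelling exactly in the pixel ratio), the
donor dims and the acceptor brightens with occupancy such that their ratio
follows the Hill response exactly, and each channel decays with its
bleaching constant. Transmitted-light movies displace the embryo texture
laterally by 40 µm for 0.5 s per event; the background outside the embryo is
unaffected.

Calibration arithmetic is exact: FOV side = (sensor/binning/split) × scale
(512 px, 4×4 binning, 12.8 µm → 1638.4 µm; 2048 px, 4×4, two half-fields,
2.9 µm → 742.4 µm) and frame rate = 1/integration rounded to one decimal
(84 ms → 11.9 Hz, 213 ms → 4.7 Hz).

## Analysis conventions

**Backgrounds.** Both "SD" terms are sample standard deviations (ddof 1):
over ROI2 pixels within a frame for GB, over the per-frame ROI1−ROI2
differences for EB. EB is clamped at zero — a background term cannot be
negative. Reference frames are caller-specified (the interactive workflow);
the automatic fallback takes the 15 frames with lowest ROI1 integrated
intensity, which slightly under-selects the glow on busy movies.

**Detection.** "Larger than 9 adjacent pixels" is read as component size
≥ 10 under 8-connectivity (the common image-analysis default); both are
configurable. Integrated density sums raw, unsubtracted pixel values over
accepted components. Event segmentation takes maximal runs of strictly
positive integrated density, merging runs separated by at most `merge_gap`
zero frames; pipelines convert a 0.5 s gap to frames at the movie's rate.

**Kinetics.** Crossings at 10/50/90% of the baseline-subtracted amplitude
are linearly interpolated between samples; the baseline is the mean of the
5 frames preceding the event window (0 when the event starts the recording).
Rising crossings anchor to the *first* upward crossing, and the peak is by
default the earliest exact maximum. On stochastic photon-limited traces, the
compartment-comparison study instead uses a small peak tolerance (earliest
frame within 10% of the maximum): on slow-decay events the absolute maximum
of a noisy near-peak plateau lands late and would otherwise bias rise and
time-to-peak upward in a decay-dependent way. Events truncated by the
recording edge keep their rise-phase statistics and are excluded from decay
statistics. Kinetic parameters are measured over a compact central somite
group, not the whole trunk, so rostro-caudal wave delays do not smear the
event shape. `resample_trace` bins by summation (photon-count semantics) and
supports integer decimation factors only; cross-rate comparisons
(4.7/11.9/30/33 Hz) are made by sampling or rendering at each rate directly.

**Contractions.** The dual-ROI ratio baseline is the whole-trace median with
a scaled-MAD spread (contractions are sparse, so the global median is the
resting level); an event is a run with |ratio − median| > k·spread
(default k = 5), and runs closer than 0.5 s are merged. Paired drug
experiments report per-embryo percent changes with mean ± SEM only — no
hypothesis testing.

**FRET.** Registration searches integer translations within ±10 px (at 4×4
binning, sub-pixel shifts are below the noise floor) and warns when the
correlation peak touches the search boundary. The donor floor defaults to
the 1st percentile of nonzero donor pixels. Bleaching is fitted by linear
least squares on log channel means of event-free frames.

**Propagation.** Onsets are 50% rising crossings with the per-ROI trace
median as baseline — frames immediately before the shared event window can
already contain the rostral ROIs' rising phase, so a pre-window mean would
bias rostral onsets late (and amplitudes low). Speed is 1/slope of an OLS
fit of onset versus distance over all grouped ROIs, with r² as a quality
flag; zero slope reports infinite speed, negative slope is flagged
caudo-rostral, and events with fewer than two valid ROIs are flagged
non-propagating and excluded from speed statistics.

## Problem sizes used by the test suite

Simulated recoveries run at deliberately compact scales: a 128×128 binned
field with 10 somites (12 for wave-speed fits, where more ROIs average the
onset-interpolation ripple of the 11.9 Hz timebase), 300–600 s recordings
for frequency recovery, 6–8 embryos with 600–900 s paired segments for the
drug cohort, and ~100–140 pooled transients from three simulated embryos for
the compartment comparison. Tolerances follow counting statistics (3 SE) for
stochastic recoveries and stated relative bands (5% for wave speed, 20% for
rise-parameter agreement) for deterministic or pooled quantities.

## What the phantom does and does not capture

The generator reproduces the statistical structure the analysis relies on:
Poisson-limited photon counting, substrate glow vs. detector noise, indicator
nonlinearity and release kinetics, photoprotein consumption, channel
bleaching, common-mode motion, wave delays and amplitude decrement. It does
not model optics (no PSF), 3-D anatomy, non-rectangular somite geometry,
autofluorescence gradients, focus drift, or developmental changes in
expression level. Passing recoveries therefore validate the analysis chain
against its own generative assumptions — they bound algorithmic error, not
biological mismatch on real movies.

## Known limitations

- The compensated refractory thinning caps realizable rates at 1/τ; the
  uncoupler presets (0.3 Hz at τ = 3 s) sit near that cap, making post-drug
  event trains more regular than Poisson.
- The detection threshold (mean + 2 SD plus glow mean) leaves the expected
  few percent of suprathreshold noise pixels; isolated ≥10-pixel noise
  clusters occasionally produce spurious one-frame events (~1 per few
  thousand frames at defaults), the pipeline's noise floor for frequency
  estimates.
- Integrated density is an extensive quantity: its apparent rise includes
  threshold-gated area growth and is not identical to the per-pixel signal
  rise, which is why kinetic comparisons use compact ROIs.
- Registration is integer-pixel and circular (np.roll); real misalignments
  at field edges would need crop-based shifting.
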