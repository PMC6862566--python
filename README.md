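# lumispark

Simulation and analysis of bioluminescent and ratiometric Ca²⁺ imaging of
spontaneous skeletal-muscle activity in zebrafish embryos.

Developing zebrafish embryos show spontaneous trunk contractions, each driven
by a cytosolic Ca²⁺ transient that is taken up by mitochondria and propagates
rostro-caudally along the somites. These events can be imaged with the
bioluminescent reporter GFP–aequorin — cytosolic (GA) or trapped in the
mitochondrial matrix (mitoGA) — at photon-limited count rates, or with the
ratiometric fluorescent indicator Twitch-4 through a split-field image
splitter. `lumispark` implements the complete analysis chain for such
recordings, paired with a ground-truthed synthetic movie generator so every
stage is testable without any microscope data.

## What it computes

**Background model and detection threshold.** Each bioluminescence frame is
thresholded at GB + EB, where the general background is estimated per frame
from an artifact-free off-embryo region (ROI2) and the embryo background
(spontaneous coelenterazine emission) once per experiment from reference
frames without visible transients:

```
GB(f) = mean(ROI2 pixels in f) + 2·SD(ROI2 pixels in f)
EB    = mean over 15 reference frames of (mean ROI1 − mean ROI2)
        + 2·SD of those per-frame differences
```

**Transient detection.** A Ca²⁺ transient is a connected component of
suprathreshold pixels over the trunk, larger than 9 adjacent pixels
(8-connectivity). Movies reduce to a per-frame *integrated density* trace
(sum of raw pixel values over accepted components), segmented into events.

**Event kinetics.** Per event: frequency, time to peak, peak amplitude, rise
time 10–90%, decay time 90–10%, half-width and duration, all from linearly
interpolated level crossings relative to the pre-event baseline.

**Contraction detection.** Transmitted-light movies are scored by the ratio
of two identical ROIs, one on a somite and one outside the embryo; a
contraction is an excursion beyond k·MAD of the baseline ratio.

**FRET processing.** Split-field movies are divided into donor and acceptor
halves, co-registered by integer translation (maximum normalized
cross-correlation), ratioed pixel by pixel above a donor floor, and
photobleaching is quantified by a mono-exponential fit to event-free frames.

**Wave propagation.** Somite ROIs grouped in threes yield per-ROI onset times
(50% rising crossings); conduction speed is 1/slope of an ordinary
least-squares fit of onset time versus centroid distance.

**Forward models in the generator.** Aequorin luminescence follows
R = pool·k·Ca^h/(K^h + Ca^h) with cooperativity h = 2.5 and photoprotein
consumption; the ratiometric response follows
ratio = r_min + (r_max − r_min)·Ca^n/(Kd^n + Ca^n) with Hill slope n = 1.04;
channel bleaching is mono-exponential with defaults giving 9% (donor) and
19% (acceptor) loss after 15 min. Events are refractory-thinned Poisson
trains; waves travel at 1.6 mm/s by default with rostro-caudal amplitude
decrement. Cameras add Poisson photon noise, gain, Gaussian read noise and
16-bit clipping.

## Worked example

```python
import numpy as np
from lumispark.phantom import (scenario_schedule, make_embryo_phantom,
                               SpikeSchedule, ScenarioFlags)
from lumispark import workbench as wb, propagation as prop

# Short recording in the second signalling period: 0.2 Hz spontaneous events,
# imaged as cytosolic luminescence at 4.7 Hz, then pushed through the full
# background → threshold → component → event chain.
rng = np.random.default_rng(7)
schedule, flags = scenario_schedule("sp2-short", duration=300.0, seed=rng)
embryo = wb.simulate_embryo("GA", schedule, flags, seed=rng, frame_rate=4.7)
freq, events, trace, bg = wb.transient_frequency(embryo.movie, embryo.phantom)
print(f"scheduled events : {schedule.n_events}")
print(f"detected events  : {len(events)}")
print(f"frequency        : {freq:.3f} Hz")
print(f"embryo background: {bg.eb:.3f} counts/pixel")

# A noiseless propagating wave at the default 1.6 mm/s, recovered by the
# grouped-ROI onset regression.
ph = make_embryo_phantom(n_somites=12)
wave = SpikeSchedule([5.0], [1.0], duration=15.0)
sim = wb.simulate_embryo("GA", wave, ScenarioFlags(), seed=0, frame_rate=11.9,
                         stochastic=False, phantom=ph)
res = prop.analyze_wave_movie(sim.movie, ph)[0]
print(f"wave speed       : {res.speed:.2f} mm/s (r² = {res.speed_fit_r2:.4f})")
```

Output:

```
scheduled events : 63
detected events  : 60
frequency        : 0.200 Hz
embryo background: 0.006 counts/pixel
wave speed       : 1.60 mm/s (r² = 1.0000)
```

The detected frequency recovers the scheduled 0.2 Hz event rate within
counting error (a few dim events fall below the photon-limited detection
threshold), the embryo background matches the simulated substrate glow per
frame, and the regression recovers the generator's conduction speed.

A command-line umbrella is also installed:

```sh
lumispark simulate --scenario sp2-short --indicator GA --seed 1 --out run/
lumispark background --movie run/GA_sp2-short.tif --roi rois.tif
lumispark detect --movie run/GA_sp2-short.tif --background background.json --roi rois.tif
```

(plus `kinetics`, `contractions`, `fret`, `propagation` and `experiment`
subcommands; see `lumispark --help`).

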