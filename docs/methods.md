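# Methods

`kymotrace` quantifies two read-outs of a neuronal imaging experiment:
directed transport of fluorescently tagged glutamate-receptor vesicles along
a neurite, and somatic calcium activity reported by GCaMP6f. Because raw
imaging data of this kind are rarely published, every analysis stage is
paired with a synthetic-data generator that produces the same kinds of
recordings with fully known ground truth; the recovery and calibration
studies below are what the test suite and `scripts/acceptance.py` compute.

## Transport simulation

A recording is a single-channel image stream of `round(duration / Δt)`
frames (default 50 s at Δt = 100 ms) over a small field containing a
neurite, modeled as a polyline of pixel vertices whose first vertex is the
cell-body end. The stationary background (uniform level *B*, default 150
counts) is multiplied by a bleach factor (default 0.1) inside a chosen
arc-length interval of the path — the photobleached segment in which dim
moving vesicles become visible. Pixels are assigned to "inside" by
nearest-point projection onto the path, so the bleached region is a band
perpendicular to the neurite.

Each vesicle is a 2D isotropic Gaussian spot (σ = 0.15 µm, amplitude 25
counts) evaluated analytically at pixel centers around its sub-pixel
position — no stamp shifting, so there are no aliasing artifacts in
velocity estimates. Motion is piecewise-constant velocity drawn uniformly
from a configured range (default 0.8–1.6 µm/s), fixed direction per vesicle
(anterograde with probability `direction_mix`), with Bernoulli pausing per
frame (default 0.05) and an optional, default-off reversal probability.
Moving vesicles are **not** attenuated by the bleach: they carry unbleached
cargo into the bleached window. Noise is applied last: Poisson shot noise on
the noiseless image, then additive Gaussian read noise (default SD 2
counts). With the default bleached background of 15 counts the per-pixel
noise SD is ≈ 4.4 counts, so the default spots sit at SNR ≈ 5.7 (amplitude /
background noise SD).

Pixel size (0.1 µm), field size, and all intensity levels are declared
defaults — the acquisition they emulate does not publish them. All
randomness flows from a mandatory per-config seed (one `SeedSequence`,
spawned into motion and noise streams); identical configs are bit-identical.

## Kymograph

The path is resampled at 1 px steps; for each frame in a half-open time
window and each sample point the kymograph records the **maximum**
bilinearly interpolated intensity over a perpendicular band of ±1 px
(3-pixel band — standard for thin neurites; max rather than mean/sum keeps
a punctum's amplitude independent of how well it is centered). Calibrations
(`frame_interval_s`, `position_step_um`, window start `t0_s`) travel with
the matrix. Position increases away from the cell body, so anterograde runs
have positive kymograph slope.

## Event detection

Detection operationalizes "count the sloped lines" in three stages:

1. **Candidates.** Rows are matched-filtered with a Gaussian of the spot
   scale (σ = 1.5 px; a real punctum spans several columns, a shot-noise
   spike one). Background per column is the temporal median; noise SD per
   column is 1.4826 × MAD of the residual (zero-MAD columns fall back to
   the global noise level, or to a sliver of the intensity range for
   noiseless data, so a constant matrix yields no candidates). Local maxima
   of the residual exceeding `detection_threshold_sd` (default 3) × SD
   become candidates, refined to sub-pixel position by parabolic
   interpolation.
2. **Linking.** Candidates are linked row-to-row by nearest neighbor within
   `max_link_jump_um` (default 0.5 µm) per elapsed frame, tolerating up to
   `max_gap_frames` (default 3) missed rows, so a briefly pausing or
   missed vesicle stays one track. Within the gate, candidates are ranked
   by distance to the track's constant-velocity prediction and established
   tracks win near-ties; leftover candidates hugging an extended track are
   treated as duplicate detections. Without these two rules a single noise
   spike landing ahead of a moving punctum seeds a parasite track that
   hijacks the run and fragments it.
3. **Filtering.** A linked track becomes a transport event iff its net
   displacement is ≥ `min_displacement_um` (2 µm), its duration is
   ≥ `min_duration_s` (0.5 s), and detections cover ≥ 60% of the rows it
   spans (`min_fill_fraction`; chance chains of noise spikes measured
   ≤ 43% occupancy versus ≈ 100% for real puncta). Velocity is the
   least-squares slope of position against time; its sign sets the
   direction.

On 40 seeded scenes of k ∈ {0..6} well-separated runs at SNR ≈ 5.7 this
recovers the exact count in 40/40 scenes, direction in 100% of matched
events, median absolute velocity error 0.09% (noiseless < 2%), and produces
0 false events in 100 empty scenes.

## Calcium trace simulation and metrics

A trace is `baseline(t) · (1 + Σ transients) + noise` over 60 s at 4 Hz
(240 samples). The baseline drifts as a slow sinusoid (default ±5% of the
100-count level, random phase); each transient is a difference-of-
exponentials kernel scaled to a drawn ΔF/F amplitude (default U(0.2, 1.0)),
with onsets stratified across the recording so events stay resolvable.
Kinetics default to a 0.5 s rise and 2.5 s decay — the multi-second somatic
events of a command interneuron, comfortably resolved at 4 Hz (a fast ~0.1 s
rise would be undersampled at this rate, and the sampled peak would
systematically miss the true one). Ground-truth peak amplitudes are stated
as the ideal ΔF/F_min of the noiseless trace at each kernel peak — the true
value of the quantity the analysis estimates — which equals the drawn kernel
amplitude exactly when drift is zero.

Metrics follow the ΔF/F_min convention: the baseline F_min is the minimum
of a 1-s boxcar-smoothed trace (a raw global minimum is an order statistic
of the noise and biases ΔF/F upward), ΔF/F = (F − F_min)/F_min, total
activity is the sum of supra-baseline fluorescence divided by the baseline
(dimensionless), and peaks are local ΔF/F maxima with prominence ≥ 0.1 and
separation ≥ 1 s. The headline per-animal amplitude statistic is the mean
ΔF/F at peaks; a whole-trace mean-ΔF/F variant is available. Per-animal
metrics are compared across groups after dividing by the untreated control
group's mean. On 50 seeded traces at 1% noise: peak count exact in 50/50,
all amplitudes within 10% (max error 8.9%).

## Statistics

Groups are screened with the **modified Thompson Tau** procedure: with
sample mean x̄ and SD *s*, the cutoff is τ·s where
τ = t₍α/2,n−2₎(n−1)/(√n·√(n−2+t²₍α/2,n−2₎)); the single most deviant point
is removed if it exceeds the cutoff (ties: larger value first) and the
procedure iterates until nothing exceeds it or n = 2. Cleaned groups are
compared with a two-tailed Student's t-test (pooled variance by default,
Welch by flag); a summary-statistics variant (from n, mean, SEM) supports
checking published values.

Two calibration facts shape the defaults, both measured by Monte Carlo and
asserted in the tests:

* At α = 0.05 the screen is aggressive on clean data: τ(20) = 1.885 sits
  below the typical maximum studentized deviation, so 78% of clean n = 20
  normal samples lose at least one point (~10% of points overall). The
  injected-outlier property is nevertheless perfect: a 10 σ point is
  removed in 500/500 trials.
* Screening at 0.05 and then t-testing inflates the test's type-I error to
  0.10–0.15 (normal or count data, n = 4–12 per group): trimmed groups
  have collapsed variance, producing spurious small p. The experiment
  layer therefore screens at a stricter default, `screen_alpha = 0.005`,
  which still removes gross (10 σ) outliers in 500/500 trials while
  keeping the two-stage procedure near its nominal size (measured
  0.053–0.068).

## End-to-end experiments and their calibration

`run_transport_experiment` simulates each animal's acquisition, builds the
kymograph, detects events restricted to the bleached segment, and compares
per-animal event counts across two groups (screen, then t-test);
`run_calcium_experiment` does the same for trace metrics normalized to the
control-group mean. Animal *i* uses `seed + i`, so a report is reproducible
from its own config echo.

The calibration studies use a compact scene — a 10 × 140 px field around a
13 µm neurite, per-animal vesicle count Poisson(8), entries uniform in
time — so that thousands of complete acquisitions are cheap; the acquisition
regime itself (50 s at 100 ms/frame) is never reduced. The null study runs
500 replicate experiments with identical group configs (4 animals/group)
and measures the rejection rate at α = 0.05; the power study runs 100
replicates with group B's vesicle rate halved (12 animals/group, the
published two-group design size). `scripts/acceptance.py` reruns these at
200/50 replicates.

## Limitations

* The simulator is a single-plane, single-channel Gaussian-PSF model: no
  optics beyond the PSF, no focus drift, no motion artifacts, no stationary
  synaptic puncta surviving the bleach, and no dual-tag rendering. Passing
  recovery tests show the analysis is correct for data matching these
  assumptions, not that it is robust to every artifact of live imaging.
* The neurite path is an input; there is no automatic tracing.
* Event detection assumes roughly constant-velocity runs; vesicles that
  reverse direction mid-window are split or mis-fit (reversals are off by
  default in the generator for the same reason).
* Calcium metrics do no spike inference, motion correction, or bleaching
  detrending beyond the smoothed-minimum baseline.
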