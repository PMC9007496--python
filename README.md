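# kymotrace

Quantitative analysis of two live-imaging read-outs used to study how
glutamate-receptor (AMPAR/GLR-1) transport is regulated in *C. elegans*
command interneurons:

1. **Vesicle transport.** A proximal stretch of the AVA neurite is
   photobleached to reveal dim GLR-1::mCherry vesicles, then imaged
   continuously (50 s at 100 ms/frame). `kymotrace` builds a calibrated
   kymograph (position × time) along the neurite, detects each directed
   vesicle run as a sloped line, classifies it as anterograde or retrograde,
   fits its velocity, and reports per-animal event counts and flux.
2. **Calcium activity.** Somatic GCaMP6f fluorescence (60 s at 250 ms/frame,
   240 samples) is reduced to ΔF/F_min = (F − F_min)/F_min with F_min the
   minimum of a smoothed trace, peak amplitudes, total activity
   (Σ max(F − F_min, 0)/F_min), and baseline, each normalizable to an
   untreated control group.

Group comparisons use the study design's statistical layer: a modified
Thompson Tau outlier screen per group,

    tau = t_{alpha/2, n-2} (n-1) / (sqrt(n) sqrt(n-2 + t_{alpha/2, n-2}^2)),

removing the most deviant point while |x − x̄| > τ·s, followed by a
two-tailed Student's t-test (pooled by default, Welch available, and a
summary-statistics variant for published n/mean/SEM values).

Because raw imaging data of this kind are typically unpublished, the package
includes a first-class synthetic-data generator (`kymotrace.simulate`) that
emulates both acquisitions with fully known ground truth — vesicles as
moving Gaussian spots with Poisson + read noise in a photobleached band, and
traces as drifting baselines with difference-of-exponentials transients —
so every stage, and the end-to-end two-group experiment, is validated by
recovery against ground truth. See `docs/methods.md` for models, parameter
defaults, and calibration measurements.

## Worked example

```python
import numpy as np
import kymotrace as kt
from kymotrace.presets import recovery_scene

# a 50 s stream with 3 staggered vesicle runs at spot SNR ~ 5.7
cfg = recovery_scene(3, seed=42)
stream, tracks = kt.simulate_transport_stream(cfg)
kymo = kt.build_kymograph(stream, kt.NeuritePath(np.asarray(cfg.path, float)))
events = kt.detect_events(kymo, restrict_to=kt.bleach_mask(kymo, cfg.bleach_window_um))
for e in events:
    print(f"{e.direction:11s} v={e.velocity_um_s:+.2f} um/s  "
          f"t=[{e.t_start_s:.1f}, {e.t_end_s:.1f}] s")
```

prints the three simulated runs, each with the correct direction and a
fitted velocity within a percent of its ground-truth 1.8/2.0/2.2 µm/s:

```
anterograde v=+1.80 um/s  t=[0.8, 7.3] s
retrograde  v=-2.00 um/s  t=[8.8, 14.7] s
anterograde v=+2.18 um/s  t=[16.6, 22.3] s
```

The statistics layer reproduces a published summary-statistics check — the
two GLR-1::mCherry reporter strains' mean neurite fluorescence (470.4 ± 66.1
SEM, n=15 vs 465.6 ± 68.2 SEM, n=11) does not differ:

```python
res = kt.t_test_from_summary(15, 470.4, 66.1, 11, 465.6, 68.2, variant="welch")
# t=0.0505, df=23.1, p=0.960  -> not significant
screen = kt.thompson_tau_screen([1, 2, 3, 4, 100], alpha=0.05)
# removed=[100.0], first cutoff tau*s = 68.53
```

The command line mirrors the library
(`kymotrace simulate-transport | kymo | events | calcium-metrics | stats |
experiment-transport | experiment-calcium`), reading JSON configs and
writing TIFF/PNG/CSV/JSON under `--out`.

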