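# bubbleflow

Quantitative contrast-enhanced ultrasound (CEUS) perfusion analysis for
microbubble bolus studies, with microvascular imaging and microbubble
morphometry.

When a bolus of gas-core microbubbles is injected intravenously, the
mean contrast intensity in a tissue region of interest — the
time-intensity curve (TIC) — rises and decays following the classic
gamma-variate model

```
I(t) = A (t - t0)^alpha exp(-(t - t0) / beta),   t > t0
```

with amplitude `A`, shape `alpha`, time scale `beta` (s) and arrival lag
`t0` (s).  `bubbleflow` fits this model to measured TICs and derives the
six standard perfusion readouts: area under the curve (relative blood
volume), wash-in and wash-out rates, mean transit time (the half-area
time of the curve, sensitive to targeted-agent retention), time of
arrival, time to peak, and peak enhancement.

Around the kinetic core the package provides:

* **SVD clutter filtering** — truncation of the leading singular
  components of the spatiotemporal (Casorati) matrix of a frame stack,
  removing high-amplitude slowly varying tissue echo;
* **ASAP microvascular imaging** — acoustic sub-aperture processing:
  the clutter-filtered Doppler signals of two receive sub-apertures are
  multiplied and averaged across frames, so correlated flow signal is
  retained while aperture-independent noise averages out as
  `1/sqrt(n_frames)`;
* **microbubble morphometry** — counting and subpixel sizing of
  dark-rimmed bubbles in brightfield haemocytometer micrographs, and
  conversion of per-field counts to suspension concentration (MB/ml);
* **a seeded synthetic-data generator** — gamma-variate boluses with an
  optional bound-pool retention component (targeted agents), paired
  sub-aperture CEUS scenes with exactly low-rank clutter, and rendered
  micrograph fields — each with exact ground truth, so the whole chain
  is verifiable without any acquisition hardware;
* **a paired cohort pipeline** — every synthetic subject receives both
  the non-targeted and the targeted agent (its own control), and arm
  differences are tested per parameter with paired t-tests and
  Bonferroni correction, or two-way ANOVA for two-group designs.

The audience is ultrasound researchers quantifying tumour perfusion and
molecular (targeted-microbubble) imaging experiments, and anyone needing
a tested, reproducible reference implementation of gamma-variate bolus
analysis or SVD/ASAP processing.

## Worked example

```python
import numpy as np
from bubbleflow import (BolusParams, GammaVariateModel, generate_tic)

# a 2 Hz, 180 s acquisition with 5%-of-peak Gaussian noise
params = BolusParams(A=1.0, alpha=2.0, beta=5.0, t0=10.0,
                     noise_sd=0.05, seed=7)
tic, truth = generate_tic(params, frame_rate=2.0, duration=180.0)

model = GammaVariateModel().fit(tic.times, tic.intensities)
print(f"alpha={model.alpha_:.3f} beta={model.beta_:.3f} t0={model.t0_:.2f}")
for name, value in model.perfusion_parameters().as_dict().items():
    print(f"{name:>18}: {value:.3f}")
```

prints

```
alpha=2.045 beta=4.904 t0=10.14
               auc: 247.684
      wash_in_rate: 2.297
     wash_out_rate: 0.804
               mtt: 12.819
   time_of_arrival: 11.516
      time_to_peak: 20.171
  peak_enhancement: 13.533
```

The fitted shape parameters recover the generating values (alpha 2,
beta 5, t0 10 s) to a few percent at this noise level.  `time_to_peak`
is `t0 + alpha*beta` (about 20 s from injection), `peak_enhancement` is
the fitted maximum `A(alpha*beta)^alpha e^-alpha ~= 13.5`, `auc` is the
closed form `A beta^(alpha+1) Gamma(alpha+1) ~= 250`, and `mtt` is the
measured curve's half-area time from arrival (about 13 s for this
shape).

An end-to-end synthetic cohort — scene synthesis, clutter filtering,
ASAP imaging, TIC fitting and paired statistics, with all artifacts on
disk:

```bash
bubbleflow simulate --subjects 6 --seed 1 --out runs/demo
```

Other entry points: `bubbleflow analyze` (recorded sub-aperture pairs),
`bubbleflow fit` (a single TIC CSV), `bubbleflow asap` (filter +
correlate two stacks), `bubbleflow mbsize` (micrograph counting/sizing
and concentration).

## Layout

```
src/bubbleflow/
  synthetic.py    seeded generators (TICs, CEUS scenes, micrographs)
  kinetics.py     gamma-variate model, fitting, perfusion parameters
  clutter.py      Casorati/SVD filtering, power Doppler, ASAP
  morphometry.py  bubble detection, sizing, concentration
  pipeline.py     cohort orchestration and statistics
  io.py, cli.py   file formats and command-line entry points
docs/methods.md   model assumptions, estimator design, limitations
```
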