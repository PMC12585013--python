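# lnkit

Linear–nonlinear cascade analysis of visual spike trains, behavioral-state
conditioning, and an integrate-and-fire Poisson simulator for interpreting
gain vs. baseline modulation — built for studies of state-dependent
processing in the early visual system (retinal ganglion cells, LGN) of
awake mice, and exercised entirely on synthetic data.

## What it does

Extracellular recordings from the awake early visual system are commonly
summarized with a linear–nonlinear (LN) cascade estimated by reverse
correlation: the spike-triggered average (STA) of a white-noise stimulus
gives the linear temporal filter (response kinetics), and the
histogram-ratio estimator

    P(response | stimulus) = N(stimulus | response) / N(stimulus) / Δt

over the stimulus projected onto the L2-normalized STA gives the static
nonlinearity (response gain). Because these measurements depend on the
animal's state, every estimator is conditioned on per-frame behavioral
masks (locomotion at 2 cm/s, pupil-size tertiles, pupil-derivative states
at ±0.01 units/s, eye stability). A companion integrate-and-fire neuron
with Poisson spiking and refractoriness,

    V(i) = G · (Σ_j L(j)·S(i−j) + B),   spike iff V_eff(i) > u_i ~ U(0,1),

separates *intrinsic* gain G and resting baseline B from the *apparent*
LN properties estimated from its spikes, which is how gain modulation is
distinguished from baseline modulation functionally.

Library modules (`src/lnkit/`):

| module | contents |
| --- | --- |
| `session` | data model (spike trains, frame-clocked stimuli, behavior), HDF5 session format, CSV export, frame binning |
| `synth` | stimulus/behavior/LN-Poisson ground-truth generators |
| `revcorr` | STA (temporal and spatial), per-bin significance, static nonlinearity, gain ratio |
| `features` | DoG peak latency, spectral peak frequency, polarity, SNR, flash PSTH analysis, 2-D Gaussian RF fits, DS/OS indices, functional typing |
| `states` | behavioral-state masks and summaries |
| `lif` | the integrate-and-fire Poisson model and the 49-cell (B, G) sweep |
| `stats` | modulation index, Wilcoxon/Kruskal–Wallis wrappers, Dunn post-hoc, gain-vs-kinetics correlation |

The numbered scripts under `analysis/` run the full pipeline end to end
(synthesize sessions → state masks → reverse correlation → simulator sweep
→ gain-kinetics correlation) and write tables under `results/`.

## Worked example

Recover a ground-truth LN neuron from its own spikes:

```python
import numpy as np
from lnkit.synth import GroundTruthNeuron, biphasic_filter, \
    gen_fullfield_noise, gen_ln_spikes
from lnkit.revcorr import compute_sta, compute_nonlinearity, passes_sta_criterion
from lnkit.lif import fit_halfwave_slope

neuron = GroundTruthNeuron(true_filter=biphasic_filter(), nl_slope=30.0,
                           nl_threshold=0.2, baseline_rate=2.0)
stim = gen_fullfield_noise(900.0, seed=3)        # 15 min of ±1 noise, 60 FPS
spikes = gen_ln_spikes(stim, neuron, seed=3)

sta = compute_sta(spikes, stim)                  # 30 lags = 500 ms window
print(spikes.n_spikes, passes_sta_criterion(sta))
print(round(float(np.dot(sta.values, neuron.true_filter)
            / np.linalg.norm(sta.values)), 4))

nl = compute_nonlinearity(spikes, stim, sta)     # bin width 0.1
m, x0 = fit_halfwave_slope(nl, min_occupancy=200)
print(round(m, 2), round(x0, 2))
```

prints

```
10264 True
0.9986
30.57 0.14
```

— 10 264 spikes, the unit passes the p < 10⁻¹⁰ STA criterion, the
estimated filter matches the generating filter with cosine similarity
0.9986, and the fitted half-wave slope 30.57 Hz/unit recovers the true
slope 30 within 2% (the threshold is smeared slightly by baseline firing).

Run the simulator sweep from the command line:

```
lnk simulate --sweep --seed 7 --out sweep.csv
```

which writes the 49-row (B, G) table of spike counts, estimated latencies,
frequencies and nonlinearity slopes. `lnk synth`, `lnk validate` and
`lnk export-csv` create and handle session files.

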