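# thalcort

A kinetic-synapse neural mass model of the visual thalamocortical loop —
the lateral geniculate nucleus (relay TCR, interneuron IN, reticular TRN
populations) coupled to layers 4 and 6 of primary visual cortex (Py4, SS4,
B4; Py6, B6) — together with the full simulation and spectral-analysis
protocol used to study brain-rhythm band transitions and an in-silico
schizophrenia condition.  It is aimed at computational neuroscientists who
want a small, fully scripted thalamocortical rhythm model: every experiment
(base state, lesions, θ/α/β transitions, ScZ case study) is a declarative
condition that can be rerun bit-for-bit from a seed.

## Model

Each population is a point ensemble.  Presynaptic voltage releases
transmitter through a sigmoid, the transmitter gates a two-state channel,
and the open fraction carries an ohmic current:

    [T]_u   = T_max / (1 + exp(-(V_u - θ_u)/σ_u))
    dr/dt   = α [T]_u (1 - r) - β r
    I_syn   = C g_max r (V_v - E_rev),   I_lk = g_lk (V_v - E_lk)
    κ dV_v/dt = - Σ_u I_syn - I_lk

with AMPA (E_rev = 0) for excitatory and GABA_A (E_rev = -85 mV, -75 mV
recurrent) for inhibitory presynaptic populations.  Connectivity strengths
C are afferent synaptic-count percentages from anatomical data; drives are
seeded Gaussian noise (means -65/-65/-75 mV, SD 2 mV) plus optional
periodic 1 ms flicker pulses for SSVEP.  Trials run 120 s on a 1 ms grid
with an adaptive Runge–Kutta–Fehlberg 4(5) integrator (numba-compiled,
~1 s per trial), and the analysis pipeline is: clip 1 s per end →
zero-phase Butterworth 1–50 Hz → Welch PSD (0.25 Hz resolution) → band
powers (θ, α-L, α-H, β-L, β-H) → paired t-tests between seed-matched
conditions.  The sigmoid parameters and membrane scale κ are calibrated
(they are not published); see `docs/methods.md` for values, rationale and
the behaviours the calibration does and does not reproduce.

## Worked example

```python
from thalcort.experiments import EXPERIMENTS, run_experiment
from thalcort.simulate import SimulationConfig

cfg = SimulationConfig(duration=60.0, n_trials=5, seed0=0)
res = run_experiment(EXPERIMENTS["base"], cfg)
print(res.summary().round(4))
```

```
      theta  alpha-low  alpha-high  beta-low  beta-high   dominant  peak_Hz  mean_mV
TCR  0.0163     0.0305      0.0153    0.0203     0.0101  alpha-low      9.0 -67.8291
Py4  0.2022     0.1921      0.0542    0.0386     0.0083      theta      9.0 -59.0062
Py6  0.2435     0.2772      0.0983    0.0937     0.0287  alpha-low      9.0 -59.1008
```

The columns are integrated band powers (mV²) of each output population,
the band with maximal power, the spectral peak, and the clipped
time/trial-mean membrane potential: in the base state the thalamic relay
and layer-6 outputs oscillate with dominant α power while layer 4 is
θ-dominant, and the boosted B6→Py6 inhibition holds Py6 near -60 mV.

The same API runs lesions and state transitions
(`EXPERIMENTS["lesion-lgn"]`, `"theta"`, `"alpha"`, `"beta"`) and the
schizophrenia comparison:

```python
from thalcort.experiments import run_scz
out = run_scz("resting", cfg)          # or "ssvep17"
print(out["tests"]["beta"].p)          # paired-t p-value, β band power
```

A thin CLI wraps the same calls:

```sh
thalcort --trials 20 --duration 120 --seed 0 experiment base
thalcort scz resting
thalcort connectivity        # CSV export of the wired base network
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities from scratch by
running the full protocol (build network → seeded noise/flicker drives →
trial batch → spectral pipeline): the base-state and pre-boost Py6 mean
potentials, the isolated-LGN TCR peak frequency, and the paired-t p-values
for the θ and β band-power changes of the schizophrenia condition against
its β-state control (resting and 17 Hz SSVEP).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
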