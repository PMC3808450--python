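# convallis

Unsupervised learning in conductance-based spiking networks with a
voltage-dependent synaptic plasticity rule.

## The problem

Cortical synapses change according to the joint activity of their pre- and
postsynaptic neurons, but classical spike-timing-dependent plasticity
(STDP) does not explain what such changes are *for*, nor several robust
slice-physiology findings (frequency-dependent tetanus outcomes, spike
triplets, repetition-frequency effects). This package implements a
normative alternative: each neuron performs stochastic gradient ascent on a
valley-shaped objective of its own subthreshold membrane potential,

  g(V) = σ₁·softplus((V−V₁)/σ₁) − c·σ₀·softplus((V−V₀)/σ₀),
  g′(V) = Φ₊(V) − Φ₋(V)  (a difference of two sigmoidal coincidence detectors),

which rewards time spent near rest or near spike threshold and penalizes
intermediate depolarization — i.e. it maximizes the *skewness* of the
membrane-potential distribution, in the spirit of projection pursuit. Each
synapse j accumulates an eligibility

  P_j(T) = s·(E_j − V_rest) ∫₀ᵀ e^−(T−t)/τp · g′(V(t)) · Σ_f ε(t − t_f) dt,

(ε: the EPSP kernel; t_f: presynaptic spike arrivals; τp = 1 s) and
expresses a weight change η·Ω(P_j) only when P leaves a dead zone
[θd, θp] = [−10, 50] (soft-threshold "shrinkage"), under a per-neuron
homeostatic firing-rate constraint implemented as a PI controller with
multiplicative synaptic scaling and a plasticity gate. A backward-in-time
lookup table evaluates all synapses' eligibilities in O(T/dt + spikes)
instead of O(n_syn·T/dt).

The package is for computational neuroscientists who want to simulate and
probe this rule family: it includes the clock-driven conductance-based
LIF/network simulator (soft reset + after-depolarization), STDP-family
baseline rules (all-to-all, nearest-neighbour, triplet), in-vitro protocol
reproductions (pairing curves, tetanus, triplets, pairing-frequency
sweeps), synthetic stimulus generators (a circular-Gaussian ring ensemble
and a multi-class cochleogram-like "digit" ensemble), recurrent-network
builders with asynchronous-irregular state calibration, and analysis
metrics with a linear spike-count readout.

## Worked example

Train one neuron on the ring ensemble (1000 excitatory inputs whose
wrapped-Gaussian rate bump jumps every 100 ms, 250 inhibitory inputs at
10 Hz) with the plasticity rule under a 10 Hz rate constraint, then inspect
what it learned:

```python
from convallis.experiment import run_gaussian_task
from convallis.metrics import subthreshold_skewness

res = run_gaussian_task(rule="convallis", duration=400_000.0, seed=0,
                        target_rate=10.0, probe_voltage=True)
print("firing rate over the final 100 s:", res["tail_rate"][0])
print("tuning index:", res["tuning_index"])
print("membrane-potential skewness:",
      subthreshold_skewness(res["probe_voltage"], res["probe_spikes"]))
```

Output (seed 0):

```
firing rate over the final 100 s: 10.28
tuning index: 0.945
membrane-potential skewness: 2.148
```

The controller holds the long-run rate at the 10 Hz target (within 3%
here); the tuning index near 1 shows the neuron now responds to a narrow
arc of the ring (it developed strong weights from one correlated input
group and silenced the rest), and the strongly positive skewness is the
objective doing its job: the membrane potential spends most of its time
near rest with brief excursions toward threshold. Training with the rate
constraint alone leaves tuning near 0.1 and skewness near 0.

In-vitro protocols run from the CLI:

```bash
convallis protocol --kind pairing --rule convallis --dt -40:40:5 --out pairing.csv
convallis calibrate --target-rate 1.5 --out calibration.json
convallis run experiment.yaml
```

The pairing CSV reproduces a biphasic STDP curve (depression for post-before-
pre lags, potentiation for pre-before-post, nothing beyond ±25 ms).

## Layout

| module | contents |
| --- | --- |
| `convallis.core_sim` | neuron/synapse/network types, numba simulation kernel, Poisson inputs |
| `convallis.plasticity` | the voltage-dependent rule: objective, eligibility (direct + fast paths), shrinkage |
| `convallis.homeostasis` | rate estimation, PI controller, plasticity gate |
| `convallis.baselines` | pair/nearest-neighbour/triplet STDP and the rcSTDP calibration search |
| `convallis.stimuli` | ring and synthetic-digit ensembles, normalization, Poisson encoding |
| `convallis.networks` | feedforward/recurrent builders, spontaneous-state calibration |
| `convallis.training` | the pattern trainer composing simulator, rules and homeostasis |
| `convallis.protocols` | in-vitro paradigms and the connectivity-vs-tuning analysis |
| `convallis.metrics` | skewness, tuning index, ANOVA F, CV-ISI, correlations, linear readout |
| `convallis.experiment` / `convallis.cli` | config-driven pipelines and the `convallis` command |
| `convallis.io` | HDF5 recordings, ensembles, networks |

See `docs/methods.md` for the model details, parameter provenance and known
limitations.
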