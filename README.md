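# v1micro

A spiking-network model of layers 2/3 of primary visual cortex for studying
how excitatory/inhibitory (E/I) imbalance reshapes cortical oscillations and
the direction of information flow between neuronal populations.  It is aimed
at computational neuroscientists who want a compact, fully seeded
microcircuit with its analysis stack — population spectra with aperiodic/
periodic decomposition, and directed phase-lag-index (dPLI) flow metrics —
in plain scientific Python.

## The model in brief

~13,000 leaky integrate-and-fire neurons in four populations: excitatory
pyramidal cells (Pyr) and the parvalbumin (PV), somatostatin (SOM) and
VIP interneuron subtypes, wired with class-pair Bernoulli connectivity
(ten allowed projections, including the VIP→SOM disinhibition motif).
Membrane dynamics follow

    dV/dt = −(V − E_l)/τ_m + I_syn/C_m,

with conductance-based AMPA/GABA synapses (`g·s·(E_rev − V)`, exponential
gates, log-normal Pyr→Pyr weights, Gaussian weights elsewhere, Gaussian
axonal delays), per-neuron Poisson background drive and a 500-fiber
feedforward stimulus pathway.  Integration is RK4 at 0.1 ms with exact
exponential gate decay.

An *E/I condition* trades neurons between Pyr and one interneuron subtype
at constant network size; the E/I ratio is n_Pyr divided by the total
interneuron count (control 10341/2916 ≈ 3.5).  Analyses operate on 2 ms
population PSTHs: trial-averaged FFT power with a FOOOF-style
aperiodic+peaks decomposition, and per-band dPLI/PLI from Hilbert phases of
band-passed, z-scored signals — dPLI(PV→Pyr) > 0.5 means PV activity leads,
< 0.5 means Pyr leads, and PLI = 2·|0.5 − dPLI| exactly.

## Worked example

```python
import v1micro as vm

scale = 0.25                                   # quarter-scale network
sizes = vm.condition_sizes("pv", 3.5, scale)   # control condition census
net = vm.build_connectivity(sizes, seed=1)
cfg = vm.SimulationConfig(duration=2000.0, scale=scale, n_trials=1)
rec = vm.integrate_trial(net, cfg, trial_seed=0)
print(vm.compute_rates(rec, cfg.analysis_window))
```

Running `python examples/02_simulate_control.py` (which adds a no-stimulus
companion trial) prints:

```
network: (2585, 335, 219, 175) neurons, 1203188 synapses
trial: 2000 ms, 15866 spikes recorded

 class  spontaneous   stimulus
   PYR       0.41 Hz     1.23 Hz
    PV      10.80 Hz    12.00 Hz
   SOM       0.68 Hz     1.07 Hz
   VIP       3.02 Hz     3.98 Hz
```

The stimulus roughly triples the sparse Pyr rate and drives PV and SOM;
activity is fluctuation-driven and inhibition-stabilized (PV carries most
of the rate).  The other example scripts build a network and check its
sampled statistics (`01`), decompose the Pyr power spectrum into an
aperiodic 1/f background plus oscillatory peaks (`03`), and compare
dPLI(PV→Pyr) between PV- and SOM-driven imbalance at E/I 4.5 (`04`).
A thin CLI mirrors these steps
(`v1micro build-network / simulate / analyze-spectra / analyze-flow /
run-experiment / report`).

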