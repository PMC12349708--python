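# Methods

## Model

`v1micro` simulates a microcircuit of layers 2/3 of primary visual cortex
as a network of leaky integrate-and-fire neurons split into four
populations: excitatory pyramidal cells (Pyr) and three inhibitory
interneuron subtypes — parvalbumin- (PV), somatostatin- (SOM) and
vasoactive-intestinal-polypeptide-expressing (VIP) cells.  The subthreshold
membrane potential of every neuron obeys

    dV/dt = -(V - E_l)/tau_m + I_syn(t)/C_m

with E_l = -70 mV, C_m = 200 pF, and class-specific membrane time constants
(Pyr 10.5 ms, PV 3.1 ms, SOM 11.8 ms, VIP 10.9 ms); PV cells are the
fast-spiking class.  A spike is emitted when V reaches -50 mV; V is then
reset to -60 mV and clamped for the class refractory period (Pyr 2 ms,
others 1 ms).  Synapses are conductance-based with exponential gating,

    ds/dt = -s/tau + sum_k delta(t - t_k - d),

each presynaptic spike incrementing the gate by one after its axonal delay
d.  Excitatory (AMPA-type) channels reverse at 0 mV, inhibitory channels at
-70 mV.  Synaptic currents are g * s * (E_rev - V); with this sign
excitatory input depolarizes and inhibitory input pulls V toward -70 mV.
(The conductance-current expression is sometimes written with the opposite
overall sign as a magnitude; the physiological direction above is what is
integrated, and it is pinned by the reversal-potential tests.)

### Circuit composition and connectivity

The control network has 13,257 neurons: 10,341 Pyr, 1,341 PV, 875 SOM and
700 VIP (E/I ratio 10341/2916 ~ 3.5).  An *E/I condition* retargets this
ratio by trading neurons between Pyr and one interneuron subtype (PV series
or SOM series) at constant total: n_pyr = round(total*r/(1+r)) and the
varied subtype absorbs the integer remainder, the other two subtypes
staying at their control counts.  The control census itself is kept as
printed rather than re-derived — it is the anchor the series is defined
against, and its achieved ratio (3.546) rounds to 3.5 but is not exactly
3.5, so no rounding rule can regenerate it from the target ratio alone.

Ten ordered class pairs carry synapses: Pyr projects to all four classes,
PV to Pyr and itself, SOM to Pyr, PV and VIP, and VIP to SOM only (the
canonical VIP-disinhibition motif).  Connection probabilities are
class-level (E->E 0.1009, E->I 0.1346, I->E 0.1689, I->I 0.1371) with
subtype weighting factors applied multiplicatively to the I->I probability
(PV->PV 1, SOM->PV 0.857, VIP->SOM 0.625, SOM->VIP 1).  Each ordered pair
is wired by independent Bernoulli draws; autapses are excluded (the source
is silent on them; excluding them is the standard microcircuit convention).

Pyr->Pyr conductances follow a long-tailed log-normal law with sigma = 1
and mu = sigma^2 + log(0.10) (median exp(mu) ~ 0.272 nS), matching the
log-normal EPSP-amplitude distributions reported for cortical pyramidal
pairs.  All other conductances are Gaussian with a 10% coefficient of
variation around pair-specific means (e.g. PV->Pyr 4.32 nS with 6.4 ms
decay, Pyr->PV 0.95 nS with 2 ms decay, SOM->Pyr 1.26 nS with 13.1 ms
decay).  Gaussian weights and delays are redrawn until positive rather than
clipped, which preserves the nominal mean to first order at these small
CVs.  Delays are Gaussian with mean d0 and variance d0/10, d0 = 2 ms for
excitatory and 1 ms for inhibitory presynaptic cells.

### External drive

Every neuron receives an independent background Poisson train (Pyr 190 Hz,
PV 770 Hz, SOM 100 Hz, VIP 150 Hz; 10 nS, 2 ms decay) for the whole trial.
The visual stimulus is a bank of 500 feedforward fibers, each an
independent 25 Hz Poisson train switched on at 100 ms, Bernoulli-connected
at probability 0.1 to Pyr and 0.01 to each interneuron class (2.5 nS, 2 ms
decay).  External arrivals act on the step of the presynaptic event with no
extra conduction delay: the delay law above is specified for intra-network
synapses, and no delay is given for the external pathways.

## Numerics

The membrane equation is integrated with classical fourth-order Runge-Kutta
at dt = 0.1 ms.  Delta-function synaptic arrivals cannot be RK4-integrated
directly, so gates advance by *exact* exponential decay once per step plus
integer arrival increments at step boundaries, and the RK4 stages see the
gates decayed to the sub-stage times (half- and full-step decay factors).
Single-neuron trajectories match the closed-form LIF solution to better
than 1e-6 mV at this step.  Per-edge delays are rounded to the dt grid with
a one-step minimum and served from a ring buffer.  Spikes are detected at
step boundaries (V >= V_thr at the end of a step), so spike times lie on
the grid.  During the refractory period V is clamped at V_reset while gates
continue to evolve.  A non-finite membrane potential aborts the trial with
a diagnostic.  The hot loop is compiled with numba; identical
(network, config, trial seed) inputs reproduce spike records exactly.

Trials are seeded hierarchically: a master seed plus (series, condition,
trial) indices feed `numpy.random.SeedSequence`, so results are independent
of how many trials or conditions are requested and every stream can be
re-derived in isolation.

The `scale` parameter multiplies population counts and the feedforward
fiber count while leaving connection probabilities and synaptic weights
untouched.  Scaled networks therefore receive proportionally less recurrent
input and are *not* dynamically equivalent to the full model; they are the
package's test and continuous-analysis configuration (see "What reduced
scale shows" below).

## Analysis stack

* **Rates** — per class, spikes in the analysis window (500 ms onward)
  divided by neuron count and window length.
* **PSTH** — population spike counts of one class in 2 ms bins over the
  analysis window (1,250 bins for a full 3 s trial).
* **Spectrum** — each trial's Pyr PSTH is smoothed with a unit-sum Gaussian
  kernel of variance 5 ms^2 (truncated at 4 SD, zero-padded edges,
  per-trial, before the transform), mean-removed, and transformed with a
  one-sided FFT; amplitude-squared spectra are averaged over trials.  The
  raw counts (not rates) enter the transform.
* **Cross-condition normalization** — within each frequency-band panel,
  min-max over the joint set of (condition, bin) powers, mapping the panel
  minimum to 0 and maximum to 1 (a per-bin variant is available by flag).
  All-equal panels return 0.5 with a warning.
* **Periodic peaks** — a compact spectral parameterization in the
  FOOOF tradition: robust log-log linear fit of the aperiodic component
  (iteratively dropping points more than one residual SD above the line),
  greedy extraction of up to three Gaussians (in linear frequency, log10
  power) from the residual with a threshold of max(2 residual SD, 0.05
  log10 units), then alternating refits and one final joint fit of line
  plus Gaussians.  On noiseless members of this generative family the
  exponent and centers are recovered essentially exactly; peak strength is
  the Gaussian height above the final aperiodic curve.  This is a
  deliberately small re-implementation (no knee parameter, at most three
  peaks), not a port of the full published tool.
* **Directed flow** — per trial and band: z-score the two PSTHs, band-pass
  with a 4th-order Butterworth applied forward-backward (zero phase),
  take instantaneous phases from the analytic signal, wrap the phase
  difference (interneuron minus Pyr) to (-pi, pi], and average the
  Heaviside step with H(0) = 1/2 (dPLI); PLI = |mean sign| with
  sign(0) = 0, so PLI = 2|0.5 - dPLI| holds exactly.  The first and last 5%
  of samples are excluded from the averages (Hilbert edge artifacts).
  Default bands are contiguous 5 Hz windows from 10 to 80 Hz (14 bands); a
  10 Hz variant is available.  Per-band means are tested against 0.5 with a
  two-sided one-sample t-test, significance tiers 0.1/0.05/0.01, no
  multiple-testing correction.

## Default protocol and reduced-scale profile

The published protocol is 50 trials of 3 s at full scale, dt 0.1 ms,
stimulus onset 100 ms, first 500 ms discarded.  The package's desk profile
uses scale 0.25, 10 trials of 2 s; the acceptance script and the headline
test use scale 0.5, 10 trials of 2 s.  These sizes keep a full condition
under ~2 minutes on one CPU while leaving enough analysis window (750
samples at 500 Hz) for the band-pass and Hilbert steps.

## What reduced scale shows — and what it does not

The reduced-scale network preserves the model's qualitative operating
regime: fluctuation-driven, inhibition-stabilized activity; stimulation
activates Pyr, PV and SOM but not VIP; a prominent gamma-band spectral peak
from the Pyr-PV loop; and Pyr-led flow toward SOM.  It does not preserve
the full oscillatory peak structure (at half scale only the gamma peak
survives aperiodic removal; the full-scale model shows three peaks, at
~24/46/67 Hz in our hands) because recurrent input scales with population
size while weights are deliberately left untouched.

Two findings of the source study reproduce here and one does not, at either
scale.  Reproduced: Pyr leads PV (dPLI < 0.5) under SOM-driven imbalance at
E/I 4.5 and in the high-gamma bands at E/I 3.0.  Not reproduced: under
PV-driven imbalance at E/I 4.5 the published model's PV activity comes to
*lead* Pyr (dPLI > 0.5 in beta/gamma), whereas in this implementation the
PV population lags the Pyr population by ~2 ms in every condition we probed
(cross-correlation peak; all 5 Hz wrapped-phase bands 20-80 Hz negative),
at full scale as well as at half scale — the beta-band phase difference
does move toward synchrony as the ratio rises (-0.29 to -0.03 rad), but it
does not cross.  The integrator, the sampled structure and the analysis
stack are each validated against closed-form and statistical oracles, so we
attribute the difference to operating-point details of the published model
that are not recoverable from its printed parameter tables (its
connectivity procedure defers to predecessor models).  The acceptance
test asserting the published direction is left failing rather than
weakened, and the acceptance script reports the measured values.

## Known limitations

* No spatial geometry, distance-dependent connectivity, gap junctions,
  synaptic plasticity, or NMDA/GABA_B receptor kinetics.
* Delays are grid-rounded; off-grid event times are out of scope.
* The spectral parameterization is the simplified variant described above.
* Scaled-down networks are not dynamically equivalent to the full model;
  conclusions about the full model should use scale 1.
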