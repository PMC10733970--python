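# ca1sim

Desk-scale compartmental modelling and analysis of rodent hippocampal CA1
pyramidal neurons. The package re-implements, end to end, a comparative
mouse/rat single-cell pipeline:

- **Ion-channel kinetics** (`ca1sim.channels`) — declarative gate schemas
  (`borg_graham`, `alpha_beta`, `inf_tau`, `calcium_hill`) with shipped
  13-channel JSON libraries and species-specific Ih presets (the mouse and
  rat h-current half-activation/time-constant parameters).
- **Morphology** (`ca1sim.morphology`) — SWC reading/writing, reduced
  species geometries, path distances, distance-dependent conductance
  distributions and synapse-site eligibility rules (thin apical dendrites
  within a species-specific path distance).
- **Cable simulator** (`ca1sim.simulator`) — Crank–Nicolson branched-cable
  integration with a Hines-style tree solve, Rush–Larsen gate updates,
  calcium pools, step currents and peak-normalized double-exponential
  synapses. The inner loop is numba-compiled (`ca1sim._kernel`).
- **Stimuli** (`ca1sim.stimuli`) — positive/negative current-clamp protocol
  suites (6 + 4 amplitudes), homogeneous Poisson synaptic trains
  (synchronous/asynchronous) and theta-gated gamma burst trains.
- **Feature extraction** (`ca1sim.features`) — spike detection at the
  −20 mV convention, spike-timing features (inv_*_ISI, mean_frequency,
  adaptation index), AP shape at threshold, subthreshold features (sag,
  deflection), membrane time constant, input resistance, and per-species
  trend/group statistics (normality-gated t-test vs rank-sum).
- **Optimization** (`ca1sim.optimize`) — two stages: a least-squares Ih +
  passive prefit on hyperpolarizing traces, then a multi-objective
  (non-dominated sorting) evolutionary fit of peak conductances against
  per-feature z-score objectives with the max-z < 3 acceptance rule.
- **Degeneracy analysis** (`ca1sim.degeneracy`) — max-normalized parameter
  heatmap matrices, PCA over a common parameter subset, and a species
  cluster-separation report on the first component.
- **Synaptic-response analysis** (`ca1sim.synaptic`) — theta/gamma drive of
  a cell through 80 AMPA synapses (0.25 nS), ISI⁻¹ distributions, the
  sharp-wave-ripple band (150–250 Hz) fraction, and the 3× synaptic-weight
  scaling experiment.
- **Synthetic data** (`ca1sim.synthetic`) — ground-truth cells with
  log-normal conductance jitter, surrogate recording sets (10 traces/cell,
  20 mouse / 53 rat cells by default), optimizer target tables, and
  two-species parameter ensembles for the PCA analysis.

## CLI

```bash
ca1sim synth --study small --seed 1 --out synth_out      # surrogate dataset
ca1sim features synth_out --out features_out             # feature TSV
ca1sim prefit-ih synth_out/mouse00 --out prefit_out      # Ih + passive fit
ca1sim optimize --species mouse --seed 1 --out opt_out   # evolutionary fit
ca1sim degeneracy --seed 1 --out deg_out                 # PCA separation
ca1sim synaptic --species mouse --rate 40 --out syn_out  # theta/gamma drive
ca1sim report --seed 1 --out report_out                  # summary JSON
```

Each command writes plain-text outputs (CSV/TSV/JSON) plus a
`manifest.json` recording the command, seeds and a config hash.

## Notes

- All randomness flows through explicit integer seeds; simulations are
  deterministic given cell + config + stimulus.
- Channel kinetics live in data files
  (`src/ca1sim/data/channels/default_{mouse,rat}.json`); the two species
  differ only in the Ih gate parameters. Conductance *densities* and
  reduced geometries are species presets in `ca1sim.presets` /
  `ca1sim.morphology` and act as synthetic-data generator ground truth,
  not as biological claims.
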