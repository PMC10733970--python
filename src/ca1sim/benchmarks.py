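"""Self-contained benchmark experiments used by the acceptance suite and the
acceptance report script.

Every function recomputes its quantity from scratch by running the package
(no stored results); all randomness flows through explicit seeds.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .channels import bg_steady_state, ih_params
from .optimize import (default_recovery_study, make_passive_ih_cell,
                       prefit_ih, run_evolution, select_and_accept)
from .presets import build_cell
from .simulator import SimulationConfig, make_single_compartment, simulate
from .stimuli import SynapticRegime
from .synaptic import SWR_BAND_HZ, run_regime
from .synthetic import generate_parameter_ensembles
from .degeneracy import cluster_separation, run_pca

__all__ = [
    "ih_half_activation_voltage",
    "prefit_experiment",
    "recovery_experiment",
    "rc_benchmark",
    "convergence_order",
    "cable_attenuation_error",
    "pca_separation_rate",
    "synaptic_band_fractions",
    "weight_scaling_fractions",
]


def ih_half_activation_voltage(species: str) -> float:
    """Numerically solve bg_steady_state(v) = 0.5 over [-120, -40] mV."""
    p = ih_params(species)
    return float(brentq(lambda v: bg_steady_state(v, p) - 0.5, -120.0,
                        -40.0, xtol=1e-10))


MOUSE_IH = dict(vhalf_l=-77.46, vhalf_t=-70.24, a0t=4.7e-3, zeta_l=3.5,
                zeta_t=7.3, gmt=0.145)


def make_prefit_traces(seed: int = 1, g_ih: float = 2e-4,
                       noise_sd: float = 0.1,
                       amplitudes=(-0.05, -0.1, -0.15, -0.2)):
    """Synthetic hyperpolarizing traces from a passive + mouse-Ih cell."""
    rng = np.random.default_rng(seed)
    traces = []
    for amp in amplitudes:
        cell = make_passive_ih_cell(**MOUSE_IH, g_ih=g_ih, g_leak_nS=10.0,
                                    e_leak=-70.0)
        cell.inject_step_current("soma", amp, 700.0, 400.0)
        tr = simulate(cell, SimulationConfig(t_stop=1300.0, dt=0.1,
                                             v_init=-70.0)).soma
        sel = tr.time >= 500.0
        tr.time = tr.time[sel] - 500.0
        tr.voltage = tr.voltage[sel]
        if noise_sd > 0:
            tr.voltage = tr.voltage + rng.normal(0.0, noise_sd,
                                                 tr.voltage.shape)
        tr.meta = dict(amplitude=amp, delay=200.0, duration=400.0,
                       protocol="HyperDePol-like")
        traces.append(tr)
    return traces


def prefit_experiment(seed: int = 1):
    """Fit the Ih + passive model (starting from the rat preset) to
    synthetic mouse-preset traces; returns (rms_error_mv, vhalf_l_error)."""
    traces = make_prefit_traces(seed=seed)
    res = prefit_ih(traces)
    return res.rms_error_mv, abs(res.parameters["vhalf_l"] - (-77.46))


def recovery_experiment(seed: int = 1, population: int = 16,
                        generations: int = 10):
    """Desk-budget evolutionary fit of a synthetic ground-truth cell;
    returns the best individual's max z-score."""
    truth, suites, targets, specs, objective = default_recovery_study(
        "mouse", seed=seed)
    archive = run_evolution(specs, objective, population=population,
                            generations=generations, seed=seed)
    best = select_and_accept(archive, k=10).individuals[0]
    return best.max_z


def rc_benchmark(dt: float = 0.025) -> float:
    """Max relative error vs the closed-form RC step response."""
    cell = make_single_compartment(c_pF=100.0, g_leak_nS=10.0, e_leak=-70.0)
    cell.inject_step_current("soma", 0.1, 100.0, 400.0)
    tr = simulate(cell, SimulationConfig(t_stop=600.0, dt=dt)).soma
    tau, dv = 10.0, 10.0
    sel = (tr.time >= 100.0) & (tr.time <= 500.0)
    expect = -70.0 + dv * (1 - np.exp(-(tr.time[sel] - 100.0) / tau))
    return float(np.max(np.abs(tr.voltage[sel] - expect)) / dv)


def convergence_order() -> float:
    """Observed temporal order from a Richardson study on the RC benchmark."""
    def rms(dt):
        cell = make_single_compartment()
        cell.inject_step_current("soma", 0.1, 10.0, 200.0)
        tr = simulate(cell, SimulationConfig(t_stop=250.0, dt=dt)).soma
        sel = (tr.time > 10.0) & (tr.time < 210.0)
        expect = -70.0 + 10.0 * (1 - np.exp(-(tr.time[sel] - 10.0) / 10.0))
        return float(np.sqrt(np.mean((tr.voltage[sel] - expect) ** 2)))

    return math.log2(rms(0.1) / rms(0.05))


def cable_attenuation_error() -> float:
    """Max relative deviation of steady-state attenuation from
    exp(-x/lambda) for x <= 2 lambda on a uniform passive cable."""
    from .morphology import Morphology, Section
    from .simulator import Cell
    diam, g_pas, ra = 2.0, 1e-4, 150.0
    lam = math.sqrt(diam * 1e-4 / (4 * ra * g_pas)) * 1e4  # um
    length = 5.2 * lam
    soma = Section("soma", "soma", 1.0, diam, diam)
    cable = Section("cable", "apical_trunk", length, diam, diam,
                    parent=soma, parent_pos=1.0)
    graph = Morphology([soma, cable]).discretize(lam / 40)
    cell = Cell(graph, [], {}, ra=ra, cm=1.0, g_pas=g_pas, e_pas=-70.0)
    cell.inject_step_current(0, 0.02, 10.0, 500.0)
    xs = np.linspace(0.2 * lam, 2.0 * lam, 8)
    idx = [0] + [graph.index_at("cable", x / length) for x in xs]
    cfg = SimulationConfig(t_stop=510.0, dt=0.1, record_sites=tuple(idx))
    res = simulate(cell, cfg)
    v = np.array([tr.voltage[-1] + 70.0 for tr in res.traces])
    x0 = graph.path_um[idx[0]]
    errs = []
    for k in range(1, len(idx)):
        expect = math.exp(-(graph.path_um[idx[k]] - x0) / lam)
        errs.append(abs(v[k] / v[0] - expect) / expect)
    return float(max(errs))


def pca_separation_rate(n_seeds: int = 100, shift_sd: float = 8.0,
                        n_per_species: int = 50, seed0: int = 0) -> float:
    """Fraction of seeds in which PC1 separates the two synthetic species
    ensembles with zero range overlap."""
    hits = 0
    for s in range(n_seeds):
        params, labels, _ = generate_parameter_ensembles(
            n_per_species=n_per_species, shift_sd=shift_sd, seed=seed0 + s)
        pca = run_pca(params)
        if cluster_separation(pca.projections, labels,
                              component=0).separated:
            hits += 1
    return hits / n_seeds


def synaptic_band_fractions(species: str, rate: float, weight_scale: float
                            = 1.0, seeds=(1, 2, 3),
                            duration: float = 2000.0, band=SWR_BAND_HZ):
    """Pooled SWR-band ISI^-1 fraction over several regime seeds (the
    reference analysis pools a set of simulations per condition)."""
    inv = []
    for seed in seeds:
        cell = build_cell(species)
        regime = SynapticRegime(rate=rate, mode="synchronous",
                                weight_scale=weight_scale,
                                duration=duration, seed=seed)
        res = run_regime(cell, regime, species=species)
        inv.append(res.distribution.inv_isi_hz)
    inv = np.concatenate(inv) if inv else np.empty(0)
    if len(inv) == 0:
        return 0.0, 0
    frac = float(np.mean((inv >= band[0]) & (inv <= band[1])))
    return frac, len(inv)


def weight_scaling_fractions(seeds=(1, 2, 3), rate: float = 80.0,
                             duration: float = 2000.0):
    """Rat-preset SWR fractions at 1x and 3x synaptic weight."""
    f1, _ = synaptic_band_fractions("rat", rate, 1.0, seeds, duration)
    f3, _ = synaptic_band_fractions("rat", rate, 3.0, seeds, duration)
    return f1, f3
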