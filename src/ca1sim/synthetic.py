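"""Generators for every input the pipeline needs without downloads:
ground-truth cells, surrogate recordings with the experimental dataset
structure, optimization targets, and two-species parameter ensembles."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .presets import (build_cell, passive_preset, region_gbar_preset)
from .simulator import SimulationConfig, simulate
from .stimuli import ProtocolSuite, make_protocol_suite
from . import features as feat

__all__ = [
    "SyntheticStudySpec",
    "GroundTruthCell",
    "make_ground_truth_cell",
    "generate_recordings",
    "generate_target_features",
    "generate_parameter_ensembles",
    "default_suites",
    "flatten_gbars",
    "unflatten_gbars",
]


def default_suites():
    return (make_protocol_suite("APwaveform-like"),
            make_protocol_suite("HyperDePol-like"))


@dataclass
class SyntheticStudySpec:
    """Fully determines a surrogate two-species dataset given its seed."""

    n_mouse: int = 20
    n_rat: int = 53
    jitter_sd_log10: float = 0.1
    noise_sd_mv: float = 0.2
    master_seed: int = 0
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.n_mouse < 1 or self.n_rat < 1:
            raise ValueError("cell counts must be >= 1")
        if self.noise_sd_mv < 0:
            raise ValueError("noise sd must be >= 0")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def flatten_gbars(region_gbars: dict) -> dict:
    """{channel: {region: g}} -> {'gbar_<channel>.<region>': g}."""
    return {f"gbar_{ch}.{reg}": g
            for ch, per in sorted(region_gbars.items())
            for reg, g in sorted(per.items())}


def unflatten_gbars(flat: dict) -> dict:
    out = {}
    for key, g in flat.items():
        name = key.removeprefix("gbar_")
        ch, reg = name.split(".")
        out.setdefault(ch, {})[reg] = g
    return out


@dataclass
class GroundTruthCell:
    """A jittered species cell plus the true parameters that made it."""

    species: str
    region_gbars: dict
    passive: dict
    seed: int
    provenance: dict = field(default_factory=dict)

    def build(self, max_seg_um: float = 20.0):
        return build_cell(self.species, region_gbars=self.region_gbars,
                          passive=self.passive, max_seg_um=max_seg_um)

    @property
    def true_parameters(self) -> dict:
        return flatten_gbars(self.region_gbars)


def make_ground_truth_cell(species: str, jitter_seed: int = 0,
                           jitter_sd_log10: float = 0.1,
                           max_redraws: int = 20) -> GroundTruthCell:
    """Species preset with log-normal conductance jitter (cell-to-cell
    variability).  Jitter keeps every conductance within one order of
    magnitude of the preset; offending draws are re-drawn."""
    base = region_gbar_preset(species)
    rng = np.random.default_rng(jitter_seed)
    jittered = {}
    redraws = 0
    for ch, per in sorted(base.items()):
        jittered[ch] = {}
        for reg, g in sorted(per.items()):
            for _ in range(max_redraws):
                f = 10.0 ** rng.normal(0.0, jitter_sd_log10)
                if 0.1 <= f <= 10.0:
                    break
                redraws += 1
            jittered[ch][reg] = g * f
    return GroundTruthCell(
        species=species, region_gbars=jittered,
        passive=passive_preset(species), seed=jitter_seed,
        provenance=dict(jitter_seed=jitter_seed,
                        jitter_sd_log10=jitter_sd_log10, redraws=redraws))


def generate_recordings(cell, suites=None, noise_sd: float = 0.2,
                        seed: int = 0, dt: float = 0.025,
                        cell_id: str = "cell0", species: str | None = None,
                        post_ms: float = 200.0):
    """One noisy somatic trace per amplitude over the protocol suites.

    ``cell`` is a :class:`GroundTruthCell` or an assembled cell.  Under the
    default suites this yields 10 traces (6 positive + 4 negative).
    """
    suites = suites or default_suites()
    if isinstance(cell, GroundTruthCell):
        species = species or cell.species
        sim_cell = cell.build()
    else:
        sim_cell = cell
    rng = np.random.default_rng(seed)
    traces = []
    for suite in suites:
        for amp in suite.amplitudes:
            sim_cell.clear_stimuli()
            sim_cell.inject_step_current("soma", amp, suite.delay,
                                         suite.duration)
            cfg = SimulationConfig(
                t_stop=suite.delay + suite.duration + post_ms, dt=dt,
                record_every=max(1, int(round(0.1 / dt))))
            res = simulate(sim_cell, cfg, meta=dict(
                amplitude=amp, delay=suite.delay, duration=suite.duration,
                protocol=suite.name, cell_id=cell_id, species=species))
            tr = res.soma
            if noise_sd > 0:
                tr.voltage = tr.voltage + rng.normal(0.0, noise_sd,
                                                     tr.voltage.shape)
            traces.append(tr)
    sim_cell.clear_stimuli()
    return traces


#: Default per-feature standard deviations attached to synthetic targets
#: (the experimental sds are not published; these set the optimizer's scale).
DEFAULT_TARGET_SDS = {
    "voltage_base": 1.0,
    "steady_state_voltage": 1.0,
    "voltage_deflection": 1.0,
    "sag_amplitude": 0.5,
    "spikecount_stimint": 1.0,
    "time_to_first_spike": 10.0,
    "time_to_last_spike": 20.0,
    "inv_first_ISI": 5.0,
    "inv_second_ISI": 5.0,
    "inv_third_ISI": 5.0,
    "inv_fourth_ISI": 5.0,
    "inv_fifth_ISI": 5.0,
    "inv_last_ISI": 5.0,
    "mean_frequency": 2.0,
}

#: Spike-time-related target set used for full-model optimization, plus the
#: subthreshold features of the negative protocol.
SPIKE_FEATURES = (
    "spikecount_stimint", "time_to_first_spike", "time_to_last_spike",
    "inv_first_ISI", "inv_second_ISI", "inv_third_ISI", "inv_fourth_ISI",
    "inv_fifth_ISI", "inv_last_ISI",
)
VOLTAGE_FEATURES = (
    "voltage_base", "steady_state_voltage", "voltage_deflection",
    "sag_amplitude",
)


def generate_target_features(cell, suites=None, sds=None, dt: float = 0.025):
    """Feature targets from noise-free traces of the ground-truth cell.

    Returns a list of target dicts {protocol, amplitude, feature, value, sd}
    directly usable by the optimizer.  Positive protocols contribute the
    spike-time features, negative protocols the voltage features.
    """
    suites = suites or default_suites()
    sds = dict(DEFAULT_TARGET_SDS, **(sds or {}))
    if any(s <= 0 for s in sds.values()):
        raise ValueError("target sds must be > 0")
    traces = generate_recordings(cell, suites=suites, noise_sd=0.0,
                                 dt=dt)
    targets = []
    dropped = []
    for tr in traces:
        values = feat.extract_all(tr)
        amp = tr.meta["amplitude"]
        wanted = SPIKE_FEATURES if amp > 0 else VOLTAGE_FEATURES
        for name in wanted:
            if name not in sds:
                continue
            if name in values:
                targets.append(dict(
                    protocol=tr.meta["protocol"], amplitude=amp,
                    feature=name, value=float(values[name]), sd=sds[name]))
            elif name == "spikecount_stimint":
                # a spike count of zero is itself informative
                targets.append(dict(
                    protocol=tr.meta["protocol"], amplitude=amp,
                    feature=name, value=0.0, sd=sds[name]))
            else:
                dropped.append((tr.meta["protocol"], amp, name))
    return targets, dropped


# ---------------------------------------------------------------------------
# Parameter ensembles for the degeneracy analysis

#: Parameters whose species means differ by default: the loadings that
#: dominate the cross-species axis (dendritic Na, axonal K_DR, somatic K_A
#: and the calcium-dependent K current).
DEFAULT_SHIFTED_PARAMETERS = (
    "gbar_Na3.apical", "gbar_KDR.axon", "gbar_KAp.soma", "gbar_KCa.soma",
)


def generate_parameter_ensembles(n_per_species: int = 100,
                                 shift_sd: float = 8.0,
                                 shifted: tuple = DEFAULT_SHIFTED_PARAMETERS,
                                 sd_log10: float = 0.15,
                                 seed: int = 0,
                                 parameters: tuple | None = None):
    """Two labeled log-normal parameter ensembles ("mouse", "rat").

    A declared subset of parameters differs in (log-)mean between species by
    ``shift_sd`` standard deviations; all others share their means.  Returns
    ``(params: DataFrame indexed by individual, labels: Series, truth)``.
    """
    import pandas as pd

    base = flatten_gbars(region_gbar_preset("mouse"))
    names = tuple(parameters) if parameters is not None else tuple(base)
    unknown = set(shifted) - set(names)
    if unknown:
        raise ValueError(f"shifted parameters not in the common set: "
                         f"{sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mu = {name: math.log10(base.get(name, 1e-4)) for name in names}
    rows, labels = [], []
    for species, sign in (("mouse", +0.5), ("rat", -0.5)):
        for _ in range(n_per_species):
            row = {}
            for name in names:
                m = mu[name]
                if name in shifted:
                    m = m + sign * shift_sd * sd_log10
                row[name] = 10.0 ** rng.normal(m, sd_log10)
            rows.append(row)
            labels.append(species)
    params = pd.DataFrame(rows)
    labels = pd.Series(labels, name="species")
    truth = dict(shifted=tuple(shifted), shift_sd=shift_sd,
                 sd_log10=sd_log10, seed=seed)
    return params, labels, truth
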