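"""In vivo-like experiments: theta/gamma synaptic drive, ISI^-1
distributions, sharp-wave-ripple band quantification and the synaptic
weight-scaling experiment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import detect_spikes
from .morphology import PLACEMENT_PRESETS, eligible_synapse_sites
from .simulator import SimulationConfig, simulate
from .stimuli import SynapticRegime

__all__ = [
    "ISIDistribution",
    "SWR_BAND_HZ",
    "AMPA_DEFAULTS",
    "run_regime",
    "isi_inverse_distribution",
    "swr_band_fraction",
    "burst_count",
    "weight_scaling_experiment",
]

SWR_BAND_HZ = (150.0, 250.0)

#: Schaffer-collateral AMPA synapse defaults (double-exponential).
AMPA_DEFAULTS = dict(tau_rise=0.5, tau_decay=3.0, weight_nS=0.25,
                     reversal=0.0)


@dataclass
class ISIDistribution:
    """Reciprocal-ISI (instantaneous frequency) distribution."""

    spike_times: np.ndarray
    inv_isi_hz: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    band_fractions: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def isi_inverse_distribution(spike_times, bins=None) -> ISIDistribution:
    """ISI^-1 = 1000/ISI_ms in Hz, histogrammed (default 0-300 Hz, 10 Hz
    bins).  Fewer than 2 spikes yield an empty distribution."""
    st = np.sort(np.asarray(spike_times, float))
    edges = np.asarray(bins, float) if bins is not None \
        else np.arange(0.0, 300.0 + 1e-9, 10.0)
    if len(st) < 2:
        return ISIDistribution(st, np.empty(0), edges,
                               np.zeros(len(edges) - 1, dtype=int))
    inv = 1000.0 / np.diff(st)
    counts, _ = np.histogram(inv, edges)
    dist = ISIDistribution(st, inv, edges, counts)
    dist.band_fractions["swr"] = swr_band_fraction(dist)
    return dist


def swr_band_fraction(dist: ISIDistribution, band=SWR_BAND_HZ):
    """Fraction of ISI^-1 values within the closed band; None when empty."""
    if len(dist.inv_isi_hz) == 0:
        return None
    lo, hi = band
    inside = (dist.inv_isi_hz >= lo) & (dist.inv_isi_hz <= hi)
    return float(np.mean(inside))


def burst_count(spike_times, max_isi_ms: float = 10.0) -> int:
    """Number of bursts: groups of consecutive ISIs below ``max_isi_ms``."""
    st = np.sort(np.asarray(spike_times, float))
    if len(st) < 2:
        return 0
    short = np.diff(st) < max_isi_ms
    return int(np.sum(short[1:] & ~short[:-1]) + (1 if short[0] else 0))


@dataclass
class RegimeResult:
    trace: object
    spike_times: np.ndarray
    distribution: ISIDistribution
    regime: SynapticRegime
    sites: list


def run_regime(cell, regime: SynapticRegime, species: str | None = None,
               placement_rule=None, dt: float = 0.025,
               synapse=None, placement_seed: int | None = None,
               settle_ms: float = 200.0) -> RegimeResult:
    """Drive ``cell`` with the synaptic regime and analyze its output.

    Synapses are placed on thin apical dendrites by the species placement
    rule, weights are 0.25 nS x ``regime.weight_scale``, spike trains come
    from the stimuli module, and spikes are detected with the -20 mV
    convention.  Fully reproducible under the regime seed.
    """
    syn = dict(AMPA_DEFAULTS, **(synapse or {}))
    if placement_rule is None:
        placement_rule = PLACEMENT_PRESETS[species or "mouse"]
    sites = eligible_synapse_sites(cell.graph, placement_rule,
                                   regime.n_synapses,
                                   regime.seed if placement_seed is None
                                   else placement_seed)
    trains = regime.trains()
    cell.clear_stimuli()
    weight = syn["weight_nS"] * regime.weight_scale
    for site, train in zip(sites, trains):
        cell.attach_double_exp_synapse(
            site, syn["tau_rise"], syn["tau_decay"], weight,
            syn["reversal"], np.asarray(train) + settle_ms)
    cfg = SimulationConfig(t_stop=regime.duration + settle_ms, dt=dt,
                           record_every=max(1, int(round(0.1 / dt))))
    res = simulate(cell, cfg, meta=dict(
        protocol=f"synaptic_{regime.mode}", rate=regime.rate,
        weight_scale=regime.weight_scale, amplitude=0.0,
        delay=settle_ms, duration=regime.duration))
    cell.clear_stimuli()
    trace = res.soma
    spikes = detect_spikes(trace)
    spikes = spikes[spikes >= settle_ms] - settle_ms
    return RegimeResult(trace=trace, spike_times=spikes,
                        distribution=isi_inverse_distribution(spikes),
                        regime=regime, sites=sites)


def weight_scaling_experiment(cell, base_regime: SynapticRegime,
                              scale_factors=(1.0, 3.0), species=None,
                              dt: float = 0.025) -> dict:
    """Re-run one regime at several synaptic weight scales with identical
    seeds and placement; report SWR-band fractions per factor and whether a
    high-frequency component appeared (> 0 fraction with >= 3 events)."""
    if any(f <= 0 for f in scale_factors):
        raise ValueError("scale factors must be > 0")
    out = {}
    for f in scale_factors:
        regime = SynapticRegime(
            rate=base_regime.rate, mode=base_regime.mode,
            n_synapses=base_regime.n_synapses, weight_scale=f,
            duration=base_regime.duration, seed=base_regime.seed,
            gamma_rate=base_regime.gamma_rate,
            spikes_per_burst=base_regime.spikes_per_burst)
        result = run_regime(cell, regime, species=species, dt=dt,
                            placement_seed=base_regime.seed)
        frac = result.distribution.band_fractions.get("swr")
        n_in_band = 0 if frac is None else int(
            round(frac * len(result.distribution.inv_isi_hz)))
        out[float(f)] = dict(
            result=result,
            swr_fraction=frac,
            n_swr_events=n_in_band,
            high_frequency_component=bool(frac and n_in_band >= 3),
        )
    return out
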