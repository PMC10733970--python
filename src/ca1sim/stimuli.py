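"""Current-clamp protocol suites and synaptic spike-train generators.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolSuite",
    "SynapticRegime",
    "make_protocol_suite",
    "poisson_trains",
    "theta_gamma_burst_trains",
]

_SUITE_DEFAULTS = {
    # 6 positive injections bracketing the depolarizing protocol range
    "APwaveform-like": dict(amplitudes=(0.15, 0.25, 0.35, 0.45, 0.55, 0.65),
                            delay=200.0, duration=400.0),
    # 4 negative injections
    "HyperDePol-like": dict(amplitudes=(-0.05, -0.10, -0.15, -0.20),
                            delay=200.0, duration=400.0),
}


@dataclass(frozen=True)
class ProtocolSuite:
    """A named family of somatic step-current injections."""

    name: str
    amplitudes: tuple      # nA
    delay: float           # ms
    duration: float        # ms

    def __post_init__(self) -> None:
        if self.name not in _SUITE_DEFAULTS:
            raise ValueError(f"unknown protocol suite {self.name!r}")
        amps = tuple(float(a) for a in self.amplitudes)
        if self.name == "APwaveform-like" and any(a <= 0 for a in amps):
            raise ValueError("APwaveform-like amplitudes must all be > 0")
        if self.name == "HyperDePol-like" and any(a >= 0 for a in amps):
            raise ValueError("HyperDePol-like amplitudes must all be < 0")
        object.__setattr__(self, "amplitudes", amps)


def make_protocol_suite(name: str, **overrides) -> ProtocolSuite:
    try:
        cfg = dict(_SUITE_DEFAULTS[name])
    except KeyError:
        raise ValueError(f"unknown protocol suite {name!r}") from None
    cfg.update(overrides)
    return ProtocolSuite(name=name, **cfg)


@dataclass(frozen=True)
class SynapticRegime:
    """A synaptic stimulation condition."""

    rate: float                      # Hz
    mode: str = "asynchronous"       # synchronous | asynchronous | theta_gamma_burst
    n_synapses: int = 80
    weight_scale: float = 1.0
    duration: float = 2000.0         # ms
    seed: int = 0
    # burst-mode extras
    gamma_rate: float = 60.0         # Hz, intra-burst rate
    spikes_per_burst: int = 5

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be > 0")
        if self.mode not in ("synchronous", "asynchronous",
                             "theta_gamma_burst"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def trains(self):
        if self.mode == "theta_gamma_burst":
            return theta_gamma_burst_trains(
                self.rate, self.gamma_rate, self.spikes_per_burst,
                self.duration, self.n_synapses, self.seed)
        return poisson_trains(self.rate, self.duration, self.n_synapses,
                              self.seed,
                              synchronous=(self.mode == "synchronous"))


def _one_poisson_train(rate_hz: float, duration_ms: float, rng) -> np.ndarray:
    mean_isi = 1000.0 / rate_hz
    n_expect = duration_ms / mean_isi
    # draw in blocks until the cumulative sum passes the duration
    times = []
    t = 0.0
    while t < duration_ms:
        block = rng.exponential(mean_isi, size=max(16, int(2 * n_expect)))
        cs = t + np.cumsum(block)
        times.append(cs[cs < duration_ms])
        t = cs[-1]
    return np.concatenate(times) if times else np.empty(0)


def poisson_trains(rate: float, duration: float, n: int, seed: int,
                   synchronous: bool = False):
    """``n`` homogeneous Poisson spike trains (ms).

    Synchronous mode replicates a single train across all synapses so the
    expected total spike count matches the asynchronous case.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be > 0")
    rng = np.random.default_rng(seed)
    if synchronous:
        train = _one_poisson_train(rate, duration, rng)
        return [train.copy() for _ in range(n)]
    return [_one_poisson_train(rate, duration, rng) for _ in range(n)]


def theta_gamma_burst_trains(theta_rate: float, gamma_rate: float,
                             spikes_per_burst: int, duration: float, n: int,
                             seed: int):
    """Bursts at gamma frequency whose onsets are Poisson at theta rate.

    Expected total rate per train is ``theta_rate * spikes_per_burst``.
    """
    if gamma_rate <= theta_rate:
        raise ValueError("gamma_rate must exceed theta_rate")
    if spikes_per_burst < 1:
        raise ValueError("spikes_per_burst must be >= 1")
    rng = np.random.default_rng(seed)
    intra = 1000.0 / gamma_rate
    out = []
    for _ in range(n):
        onsets = _one_poisson_train(theta_rate, duration, rng)
        spikes = (onsets[:, None] + intra * np.arange(spikes_per_burst)[None, :]
                  ).ravel()
        out.append(np.sort(spikes[spikes < duration]))
    return out
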