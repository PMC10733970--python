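"""Voltage- and calcium-dependent membrane conductance kinetics.

Gating schemes are declarative (:class:`GateSpec`) so that channel libraries
live in JSON data files rather than code.  Four functional forms are
supported:

``borg_graham``
    Thermodynamic gating with effective charges: the steady state is a
    Boltzmann function of voltage and the time constant is an asymmetric
    exponential ratio controlled by a charge ``zeta_t`` and an asymmetry
    factor ``gmt``.
``inf_tau``
    Boltzmann steady state plus a bell-shaped (sech) time constant.
``alpha_beta``
    Exponential forward/backward rates.
``calcium_hill``
    Hill function of the local calcium pool with a fixed time constant.

The h-current (Ih) species presets ship as :func:`make_ih_preset`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "K_PER_MV",
    "BorgGrahamParams",
    "GateSpec",
    "ChannelSpec",
    "CalciumPool",
    "bg_steady_state",
    "bg_time_constant",
    "make_ih_preset",
    "ih_params",
    "evaluate_channel",
    "load_channel_definitions",
    "save_channel_definitions",
    "default_channel_library",
    "CHANNEL_NAMES",
]

# F/(R*T) per millivolt at the 33 degC recording temperature (pinned).
K_PER_MV = 0.0378

#: The full channel family used by the reduced models.
CHANNEL_NAMES = (
    "Nax", "Na3", "KDR", "KAp", "KAd", "KM", "KD",
    "CaN", "CaL", "CaT", "KCa", "Cagk", "Ih",
)

GATE_FORMS = ("borg_graham", "alpha_beta", "inf_tau", "calcium_hill")

_REQUIRED_PARAMS = {
    "borg_graham": ("vhalf_l", "vhalf_t", "a0t", "zeta_l", "zeta_t", "gmt"),
    "alpha_beta": ("vhalf", "a_rate", "a_slope", "b_rate", "b_slope"),
    "inf_tau": ("vhalf", "slope", "tau_min", "tau_amp", "tau_vhalf", "tau_sigma"),
    "calcium_hill": ("k_half", "hill", "tau"),
}


@dataclass(frozen=True)
class BorgGrahamParams:
    """Parameters of one thermodynamic (Borg-Graham style) gate.

    ``clk`` is stored and reported but by default does not enter the rate
    equations (its functional role in the source fits is undocumented);
    ``clk_mode`` lets it act on ``a0t`` for sensitivity studies:
    ``"divide_a0t"`` speeds the gate up for clk < 1, ``"multiply_a0t"``
    slows it down.
    """

    vhalf_l: float          # mV, steady-state half-activation
    vhalf_t: float          # mV, time-constant midpoint
    a0t: float              # 1/ms, rate scale
    zeta_l: float           # effective charge of the steady state
    zeta_t: float           # effective charge of the rate
    gmt: float              # rate asymmetry, in (0, 1)
    clk: float = 1.0        # auxiliary scale (role under-specified; inert by default)
    temperature_factor: float = 1.0
    clk_mode: str = "inert"  # one of {inert, divide_a0t, multiply_a0t}

    def __post_init__(self) -> None:
        if not (self.a0t > 0):
            raise ValueError("a0t must be > 0")
        if not (self.temperature_factor > 0):
            raise ValueError("temperature_factor must be > 0")
        if not (0.0 < self.gmt < 1.0):
            raise ValueError("gmt must lie in (0, 1)")
        if self.clk_mode not in ("inert", "divide_a0t", "multiply_a0t"):
            raise ValueError(f"unknown clk_mode {self.clk_mode!r}")

    @property
    def effective_a0t(self) -> float:
        if self.clk_mode == "divide_a0t":
            return self.a0t / self.clk
        if self.clk_mode == "multiply_a0t":
            return self.a0t * self.clk
        return self.a0t


def _check_finite(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage must be finite")
    return arr


def bg_steady_state(v, p: BorgGrahamParams, k: float = K_PER_MV):
    """Steady-state activation 1/(1 + exp(k*zeta_l*(v - vhalf_l))).

    Strictly decreasing in ``v`` for ``zeta_l > 0`` (hyperpolarization-
    activated convention, as for Ih); tends to 1 as v -> -inf.
    """
    arr = _check_finite(v)
    out = 1.0 / (1.0 + np.exp(k * p.zeta_l * (arr - p.vhalf_l)))
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def bg_time_constant(v, p: BorgGrahamParams, k: float = K_PER_MV):
    """Activation time constant in ms.

    tau(v) = exp(k*zeta_t*gmt*(v - vhalf_t))
             / (temperature_factor * a0t * (1 + exp(k*zeta_t*(v - vhalf_t))))
    """
    arr = _check_finite(v)
    num = np.exp(k * p.zeta_t * p.gmt * (arr - p.vhalf_t))
    den = p.temperature_factor * p.effective_a0t * (
        1.0 + np.exp(k * p.zeta_t * (arr - p.vhalf_t))
    )
    out = num / den
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


@dataclass
class GateSpec:
    """One gating variable of a channel."""

    name: str
    power: int
    form: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError(f"gate {self.name}: power must be >= 0")
        if self.form not in GATE_FORMS:
            raise ValueError(f"gate {self.name}: unknown form {self.form!r}")
        missing = [
            p for p in _REQUIRED_PARAMS[self.form] if p not in self.parameters
        ]
        if missing:
            raise ValueError(
                f"gate {self.name} ({self.form}): missing parameters {missing}"
            )

    # -- kinetics -----------------------------------------------------------

    def bg_params(self) -> BorgGrahamParams:
        if self.form != "borg_graham":
            raise ValueError("not a borg_graham gate")
        p = self.parameters
        return BorgGrahamParams(
            vhalf_l=p["vhalf_l"], vhalf_t=p["vhalf_t"], a0t=p["a0t"],
            zeta_l=p["zeta_l"], zeta_t=p["zeta_t"], gmt=p["gmt"],
            clk=p.get("clk", 1.0),
            temperature_factor=p.get("temperature_factor", 1.0),
            clk_mode=p.get("clk_mode", "inert"),
        )

    def steady_state(self, v, ca: float = 1e-4):
        p = self.parameters
        if self.form == "borg_graham":
            return bg_steady_state(v, self.bg_params())
        if self.form == "inf_tau":
            x = 1.0 / (1.0 + np.exp((p["vhalf"] - np.asarray(v, float))
                                    / p["slope"]))
            floor = p.get("floor", 0.0)
            return floor + (1.0 - floor) * x
        if self.form == "alpha_beta":
            a, b = self._rates(v)
            return a / (a + b)
        if self.form == "calcium_hill":
            can = float(ca) ** p["hill"]
            return can / (can + p["k_half"] ** p["hill"])
        raise AssertionError(self.form)

    def time_constant(self, v, ca: float = 1e-4):
        p = self.parameters
        if self.form == "borg_graham":
            tau = bg_time_constant(v, self.bg_params())
            return np.maximum(tau, p.get("tau_min", 0.0))
        if self.form == "inf_tau":
            x = (np.asarray(v, float) - p["tau_vhalf"]) / p["tau_sigma"]
            return p["tau_min"] + p["tau_amp"] / (np.exp(x) + np.exp(-x))
        if self.form == "alpha_beta":
            a, b = self._rates(v)
            return np.maximum(1.0 / (a + b), p.get("tau_min", 0.0))
        if self.form == "calcium_hill":
            return np.full_like(np.asarray(v, float), p["tau"], dtype=float)
        raise AssertionError(self.form)

    def _rates(self, v):
        p = self.parameters
        dv = np.asarray(v, float) - p["vhalf"]
        a = p["a_rate"] * np.exp(dv / p["a_slope"])
        b = p["b_rate"] * np.exp(-dv / p["b_slope"])
        return a, b

    @property
    def is_calcium_dependent(self) -> bool:
        return self.form == "calcium_hill" or "ca_shift_per_decade" in self.parameters


@dataclass
class ChannelSpec:
    """A membrane conductance: named gates plus a reversal potential."""

    name: str
    gates: list
    reversal: float | str  # mV, or the string "calcium" for Ca channels
    calcium_flux_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.calcium_flux_fraction <= 1.0):
            raise ValueError("calcium_flux_fraction must lie in [0, 1]")
        self.gates = [
            g if isinstance(g, GateSpec) else GateSpec(**g) for g in self.gates
        ]

    @property
    def reversal_mv(self) -> float:
        # Ohmic approximation for Ca channels (GHK out of scope).
        return 120.0 if self.reversal == "calcium" else float(self.reversal)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reversal": self.reversal,
            "calcium_flux_fraction": self.calcium_flux_fraction,
            "gates": [asdict(g) for g in self.gates],
        }


@dataclass
class CalciumPool:
    """First-order calcium extrusion: exponential decay toward rest."""

    decay_tau: float = 100.0                   # ms
    resting_concentration: float = 1e-4        # mM (100 nM)
    current_to_concentration_gain: float = 0.0518  # mM per (mA/cm^2 * ms)

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")


# ---------------------------------------------------------------------------
# Ih species presets (values fitted to the two species' recordings)

_IH_PRESETS = {
    "mouse": dict(vhalf_l=-77.46, vhalf_t=-70.24, a0t=4.7e-3,
                  zeta_l=3.5, zeta_t=7.3, gmt=0.145, clk=0.24),
    "rat": dict(vhalf_l=-69.5, vhalf_t=-64.1, a0t=7.2e-3,
                zeta_l=5.2, zeta_t=15.8, gmt=0.067, clk=1.0),
}


def ih_params(species: str, clk_mode: str = "inert") -> BorgGrahamParams:
    """The fitted Ih gate parameters for ``species`` in {mouse, rat}."""
    try:
        p = _IH_PRESETS[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None
    return BorgGrahamParams(**p, clk_mode=clk_mode)


def make_ih_preset(species: str, reversal: float = -30.0) -> ChannelSpec:
    """Single borg_graham gate, power 1, carrying the species preset values."""
    p = ih_params(species)
    gate = GateSpec(
        name="h", power=1, form="borg_graham",
        parameters=dict(vhalf_l=p.vhalf_l, vhalf_t=p.vhalf_t, a0t=p.a0t,
                        zeta_l=p.zeta_l, zeta_t=p.zeta_t, gmt=p.gmt, clk=p.clk),
    )
    return ChannelSpec(name="Ih", gates=[gate], reversal=reversal)


# ---------------------------------------------------------------------------
# Channel evaluation (reference, unvectorized path; the cable simulator uses
# tabulated kinetics compiled separately)

def evaluate_channel(gate_values, v: float, ca: float, spec: ChannelSpec,
                     gbar: float):
    """Instantaneous current density and gate derivatives.

    Returns ``(i, didt)`` where ``i`` is the ohmic current density in
    mA/cm^2 (positive outward) and ``didt`` the per-gate derivatives
    ``(x_inf - x)/tau`` in 1/ms.  Calcium-permeable channels contribute
    ``calcium_flux_fraction * i`` to the calcium pool.
    """
    gate_values = np.asarray(gate_values, dtype=float)
    if gate_values.shape != (len(spec.gates),):
        raise ValueError("one state value per gate required")
    if np.any((gate_values < 0) | (gate_values > 1)):
        raise ValueError("gate values must lie in [0, 1]")
    if gbar < 0:
        raise ValueError("gbar must be >= 0")
    open_frac = 1.0
    derivs = np.empty_like(gate_values)
    for j, gate in enumerate(spec.gates):
        open_frac *= gate_values[j] ** gate.power
        xinf = gate.steady_state(v, ca)
        tau = max(float(gate.time_constant(v, ca)), 1e-9)
        derivs[j] = (xinf - gate_values[j]) / tau
    current = gbar * open_frac * (v - spec.reversal_mv)
    return current, derivs


# ---------------------------------------------------------------------------
# Channel library I/O

def _validate_library(specs: list) -> list:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate channel names: {dupes}")
    return specs


def load_channel_definitions(path) -> list:
    """Load a channel library from a JSON file; validates against the schema."""
    with open(path) as fh:
        doc = json.load(fh)
    channels = doc["channels"] if isinstance(doc, dict) else doc
    specs = [ChannelSpec(**entry) for entry in channels]
    return _validate_library(specs)


def save_channel_definitions(specs, path) -> None:
    doc = {"channels": [s.to_dict() for s in specs]}
    Path(path).write_text(json.dumps(doc, indent=1))


def default_channel_library(species: str) -> list:
    """The shipped 13-channel library for ``species`` in {mouse, rat}."""
    if species not in ("mouse", "rat"):
        raise ValueError(f"unknown species {species!r}")
    path = Path(__file__).parent / "data" / "channels" / f"default_{species}.json"
    return load_channel_definitions(path)
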