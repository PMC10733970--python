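"""Deterministic integration of the branched cable equation.

The solver uses tree-ordered Gaussian elimination (one downward and one
upward sweep per step) with a theta rule for the voltage (Crank-Nicolson by
default) and exponential updates for the gating variables, staggered at half
steps.  Channel kinetics are tabulated once per cell on a uniform voltage
grid; the stepping itself is compiled (see :mod:`ca1sim._kernel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .channels import CalciumPool, ChannelSpec
from .morphology import CompartmentGraph, Morphology

__all__ = [
    "SimulationConfig",
    "VoltageTrace",
    "Cell",
    "assemble",
    "make_single_compartment",
    "exp2syn_peak_time",
    "simulate",
]

V_TABLE_MIN, V_TABLE_MAX, V_TABLE_STEP = -150.0, 70.0, 0.05


@dataclass
class SimulationConfig:
    t_stop: float
    dt: float = 0.025
    v_init: float = -70.0
    method: str = "crank_nicolson"
    record_sites: tuple = ("soma",)
    record_every: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_stop < self.dt:
            raise ValueError("t_stop must be >= dt")
        if self.method not in ("crank_nicolson", "implicit_euler"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def theta(self) -> float:
        return 0.5 if self.method == "crank_nicolson" else 1.0


@dataclass
class VoltageTrace:
    """A recorded (or synthetic) voltage trace plus stimulus metadata."""

    time: np.ndarray      # ms, uniform
    voltage: np.ndarray   # mV
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def stimulus_window(self) -> tuple:
        d = self.meta["delay"]
        return d, d + self.meta["duration"]


class _GateTables:
    """Deduplicated xinf/tau tables for all voltage-dependent gates."""

    def __init__(self):
        self.keys = {}
        self.inf = []
        self.tau = []
        self.grid = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2,
                              V_TABLE_STEP)

    def index_for(self, channel_name: str, gate) -> int:
        key = (channel_name, gate.name)
        if key not in self.keys:
            self.keys[key] = len(self.inf)
            self.inf.append(np.asarray(gate.steady_state(self.grid), float))
            self.tau.append(np.maximum(
                np.asarray(gate.time_constant(self.grid), float), 1e-6))
        return self.keys[key]


class Cell:
    """A simulatable cell: compartment arrays plus attached stimuli."""

    def __init__(self, graph: CompartmentGraph, channels, density,
                 ra=150.0, cm=1.0, g_pas=5e-5, e_pas=-70.0,
                 calcium: CalciumPool | None = None):
        self.graph = graph
        self.channels = {c.name: c for c in channels}
        self.density = density
        n = graph.n
        self.parent = graph.parent.copy()
        self.parent[0] = 0
        self.g_ax = graph.axial_conductance(ra)
        self.g_ax_sum = self.g_ax.copy()
        for i in range(1, n):
            self.g_ax_sum[graph.parent[i]] += self.g_ax[i]
        self.c_abs = _per_region(cm, graph) * 1e-3 * graph.area_cm2
        self.g_pas_abs = _per_region(g_pas, graph) * graph.area_cm2
        self.e_pas = _per_region(e_pas, graph)
        self.calcium = calcium or CalciumPool()

        tables = _GateTables()
        gate_comp, gate_kind, gate_table, gate_power = [], [], [], []
        gate_hill_k, gate_hill_n, gate_tau_const = [], [], []
        gate_ca_shift, gate_ca_ref = [], []
        inst_comp, inst_gmax, inst_erev, inst_caflux = [], [], [], []
        inst_gate_start, inst_ngates = [], []
        has_ca = np.zeros(n, dtype=np.bool_)

        for name, dens in density.items():
            spec = self.channels[name]
            if spec.calcium_flux_fraction > 0:
                has_ca |= dens > 0
            for c in np.flatnonzero(dens > 0):
                inst_comp.append(c)
                inst_gmax.append(dens[c] * graph.area_cm2[c])
                inst_erev.append(spec.reversal_mv)
                inst_caflux.append(spec.calcium_flux_fraction)
                inst_gate_start.append(len(gate_comp))
                inst_ngates.append(len(spec.gates))
                for gate in spec.gates:
                    gate_comp.append(c)
                    gate_power.append(gate.power)
                    p = gate.parameters
                    if gate.form == "calcium_hill":
                        gate_kind.append(_kernel.KIND_CA_HILL)
                        gate_table.append(0)
                        gate_hill_k.append(p["k_half"])
                        gate_hill_n.append(float(p["hill"]))
                        gate_tau_const.append(p["tau"])
                        gate_ca_shift.append(0.0)
                        gate_ca_ref.append(1.0)
                    elif "ca_shift_per_decade" in p:
                        gate_kind.append(_kernel.KIND_CA_SHIFTED_VTABLE)
                        gate_table.append(tables.index_for(name, gate))
                        gate_hill_k.append(0.0)
                        gate_hill_n.append(0.0)
                        gate_tau_const.append(0.0)
                        gate_ca_shift.append(p["ca_shift_per_decade"])
                        gate_ca_ref.append(p.get("ca_ref", 1e-3))
                        has_ca[c] = True
                    else:
                        gate_kind.append(_kernel.KIND_VTABLE)
                        gate_table.append(tables.index_for(name, gate))
                        gate_hill_k.append(0.0)
                        gate_hill_n.append(0.0)
                        gate_tau_const.append(0.0)
                        gate_ca_shift.append(0.0)
                        gate_ca_ref.append(1.0)

        self.tab_inf = (np.vstack(tables.inf) if tables.inf
                        else np.zeros((1, 2)))
        self.tab_tau = (np.vstack(tables.tau) if tables.tau
                        else np.ones((1, 2)))
        self._tables = tables
        self.gate_comp = np.array(gate_comp, dtype=np.int64)
        self.gate_kind = np.array(gate_kind, dtype=np.int64)
        self.gate_table = np.array(gate_table, dtype=np.int64)
        self.gate_power = np.array(gate_power, dtype=np.int64)
        self.gate_hill_k = np.array(gate_hill_k, dtype=float)
        self.gate_hill_n = np.array(gate_hill_n, dtype=float)
        self.gate_tau_const = np.array(gate_tau_const, dtype=float)
        self.gate_ca_shift = np.array(gate_ca_shift, dtype=float)
        self.gate_ca_ref = np.array(gate_ca_ref, dtype=float)
        self.inst_comp = np.array(inst_comp, dtype=np.int64)
        self.inst_gmax = np.array(inst_gmax, dtype=float)
        self.inst_erev = np.array(inst_erev, dtype=float)
        self.inst_caflux = np.array(inst_caflux, dtype=float)
        self.inst_gate_start = np.array(inst_gate_start, dtype=np.int64)
        self.inst_ngates = np.array(inst_ngates, dtype=np.int64)
        self.has_ca = has_ca
        # gain converts absolute calcium current (mA) to mM/ms: density
        # gain / area
        with np.errstate(divide="ignore"):
            self.ca_gain_abs = np.where(
                has_ca,
                self.calcium.current_to_concentration_gain / graph.area_cm2,
                0.0)
        self.ca_rest = np.full(n, self.calcium.resting_concentration)
        self.ca_tau = np.full(n, self.calcium.decay_tau)

        self.stimuli = []   # (comp, amp_nA, delay, duration)
        self.synapses = []  # dicts
        self._init_state = None

    @property
    def n_gates(self) -> int:
        return len(self.gate_comp)

    # -- stimuli ------------------------------------------------------------

    def resolve_site(self, site) -> int:
        if isinstance(site, str):
            if site == "soma":
                return self.graph.soma_index
            return self.graph.index_at(site, 0.5)
        idx = int(site)
        if not (0 <= idx < self.graph.n):
            raise ValueError(f"unknown site {site!r}")
        return idx

    def inject_step_current(self, site, amplitude_nA: float, delay: float,
                            duration: float) -> None:
        self.stimuli.append((self.resolve_site(site), amplitude_nA,
                             delay, duration))

    def attach_double_exp_synapse(self, site, tau_rise: float,
                                  tau_decay: float, weight_nS: float,
                                  reversal: float, spike_times) -> None:
        """Conductance synapse: normalized difference of exponentials whose
        peak equals ``weight_nS`` for a single spike."""
        if not (tau_decay > tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if weight_nS < 0:
            raise ValueError("weight must be >= 0")
        self.synapses.append(dict(
            comp=self.resolve_site(site), tau1=tau_rise, tau2=tau_decay,
            weight_S=weight_nS * 1e-9, reversal=reversal,
            spike_times=np.sort(np.asarray(spike_times, dtype=float)),
        ))

    def clear_stimuli(self) -> None:
        self.stimuli = []
        self.synapses = []

    def set_initial_state(self, state) -> None:
        self._init_state = state

    # -- state --------------------------------------------------------------

    def initial_state(self, v_init: float):
        if self._init_state is not None:
            v, gates, ca = self._init_state
            return v.copy(), gates.copy(), ca.copy()
        v = np.full(self.graph.n, float(v_init), dtype=float)
        ca = self.ca_rest.copy()
        gates = np.empty(self.n_gates)
        for g in range(self.n_gates):
            kind = self.gate_kind[g]
            c = self.gate_comp[g]
            if kind == _kernel.KIND_CA_HILL:
                can = ca[c] ** self.gate_hill_n[g]
                gates[g] = can / (can + self.gate_hill_k[g]
                                  ** self.gate_hill_n[g])
            else:
                vv = v[c]
                if kind == _kernel.KIND_CA_SHIFTED_VTABLE:
                    vv -= self.gate_ca_shift[g] * math.log10(
                        max(ca[c], 1e-9) / self.gate_ca_ref[g])
                gates[g] = float(np.interp(
                    vv, self._tables.grid, self.tab_inf[self.gate_table[g]]))
        return v, gates, ca


def _per_region(value, graph: CompartmentGraph) -> np.ndarray:
    if isinstance(value, dict):
        out = np.empty(graph.n)
        for reg in np.unique(graph.region):
            if reg not in value:
                raise ValueError(f"no value for region {reg!r}")
            out[graph.region == reg] = value[reg]
        return out
    return np.full(graph.n, float(value))


def assemble(morph, density, channels, ra=150.0, cm=1.0, g_pas=5e-5,
             e_pas=-70.0, calcium: CalciumPool | None = None,
             max_seg_um: float = 20.0) -> Cell:
    """Build a simulatable cell from geometry, densities and a channel set.

    ``density`` maps channel name to a per-compartment array (see
    :func:`ca1sim.morphology.apply_distributions`); every referenced channel
    must exist in ``channels``.
    """
    graph = morph.discretize(max_seg_um) if isinstance(morph, Morphology) \
        else morph
    by_name = {c.name: c for c in channels}
    for name, dens in density.items():
        if name not in by_name:
            raise ValueError(f"density refers to unknown channel {name!r}")
        if np.asarray(dens).shape != (graph.n,):
            raise ValueError(f"density for {name!r} must cover every "
                             f"compartment exactly once")
    return Cell(graph, channels, density, ra=ra, cm=cm, g_pas=g_pas,
                e_pas=e_pas, calcium=calcium)


def make_single_compartment(c_pF=100.0, g_leak_nS=10.0, e_leak=-70.0,
                            channels=(), density_S_cm2=None,
                            cm_uF_cm2=1.0) -> Cell:
    """Convenience: an isopotential cell with given total C and leak."""
    area_cm2 = c_pF * 1e-6 / cm_uF_cm2  # pF -> uF
    diam_um = math.sqrt(area_cm2 * 1e8 / math.pi)  # L = diam cylinder
    from .morphology import Section
    sec = Section("soma", "soma", diam_um, diam_um, diam_um)
    graph = Morphology([sec]).discretize(max_seg_um=1e9)
    g_pas = g_leak_nS * 1e-9 / graph.area_cm2[0]
    dens = {}
    if density_S_cm2:
        for name, val in density_S_cm2.items():
            dens[name] = np.full(1, val)
    return Cell(graph, channels, dens, g_pas=g_pas, e_pas=e_leak,
                cm=cm_uF_cm2)


def exp2syn_peak_time(tau1: float, tau2: float) -> float:
    return tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)


@dataclass
class SimResult:
    traces: list
    final_state: tuple
    status: int

    @property
    def soma(self) -> VoltageTrace:
        return self.traces[0]


def simulate(cell: Cell, config: SimulationConfig, meta=None) -> SimResult:
    """Integrate the cell under its attached stimuli.

    Deterministic given cell + config; raises on numerical instability.
    """
    record_idx = np.array([cell.resolve_site(s)
                           for s in config.record_sites], dtype=np.int64)
    v, gates, ca = cell.initial_state(config.v_init)

    nst = len(cell.stimuli)
    stim_comp = np.array([s[0] for s in cell.stimuli], dtype=np.int64)
    stim_amp = np.array([s[1] * 1e-6 for s in cell.stimuli], dtype=float)
    stim_delay = np.array([s[2] for s in cell.stimuli], dtype=float)
    stim_dur = np.array([s[3] for s in cell.stimuli], dtype=float)

    nsyn = len(cell.synapses)
    syn_comp = np.array([s["comp"] for s in cell.synapses], dtype=np.int64)
    syn_tau1 = np.array([s["tau1"] for s in cell.synapses], dtype=float)
    syn_tau2 = np.array([s["tau2"] for s in cell.synapses], dtype=float)
    syn_erev = np.array([s["reversal"] for s in cell.synapses], dtype=float)
    events = []
    for si, s in enumerate(cell.synapses):
        tp = exp2syn_peak_time(s["tau1"], s["tau2"])
        factor = 1.0 / (math.exp(-tp / s["tau2"]) - math.exp(-tp / s["tau1"]))
        for t in s["spike_times"]:
            events.append((t, si, s["weight_S"] * factor))
    events.sort()
    ev_time = np.array([e[0] for e in events], dtype=float)
    ev_syn = np.array([e[1] for e in events], dtype=np.int64)
    ev_amp = np.array([e[2] for e in events], dtype=float)

    nsteps = int(round(config.t_stop / config.dt))
    out_t, out_v, status = _kernel.run(
        cell.parent, cell.g_ax, cell.g_ax_sum, cell.c_abs, cell.g_pas_abs,
        cell.e_pas,
        cell.tab_inf, cell.tab_tau, V_TABLE_MIN, 1.0 / V_TABLE_STEP,
        cell.gate_comp, cell.gate_kind, cell.gate_table, cell.gate_power,
        cell.gate_hill_k, cell.gate_hill_n, cell.gate_tau_const,
        cell.gate_ca_shift, cell.gate_ca_ref, gates,
        cell.inst_comp, cell.inst_gmax, cell.inst_erev, cell.inst_caflux,
        cell.inst_gate_start, cell.inst_ngates,
        ca, cell.has_ca, cell.ca_rest, cell.ca_tau, cell.ca_gain_abs,
        stim_comp, stim_amp, stim_delay, stim_dur,
        syn_comp, np.zeros(nsyn), np.zeros(nsyn), syn_tau1, syn_tau2,
        syn_erev,
        ev_time, ev_syn, ev_amp,
        v, config.dt, nsteps, config.theta, record_idx, config.record_every,
    )
    if status == 0 and not np.isfinite(out_v).all():
        status = 1
    if status != 0:
        raise FloatingPointError(
            "simulation became unstable (non-finite state); "
            f"t_stop={config.t_stop}, dt={config.dt}")
    traces = [VoltageTrace(out_t, out_v[r], dict(meta or {}))
              for r in range(len(record_idx))]
    return SimResult(traces=traces, final_state=(v, gates, ca),
                     status=status)
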