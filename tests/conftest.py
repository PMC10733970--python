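import numpy as np
import pytest

from ca1sim.morphology import Morphology, Section
from ca1sim.simulator import SimulationConfig, VoltageTrace, simulate


@pytest.fixture(scope="session")
def mouse_cell():
    from ca1sim.presets import build_cell
    return build_cell("mouse")


@pytest.fixture(scope="session")
def rat_cell():
    from ca1sim.presets import build_cell
    return build_cell("rat")


@pytest.fixture()
def toy_swc(tmp_path):
    """Soma (r=5 um) plus one apical segment of length 10 um."""
    path = tmp_path / "toy.swc"
    path.write_text(
        "# toy\n"
        "1 1 0 0 0 5.0 -1\n"
        "2 4 0 10 0 1.0 1\n"
    )
    return path


@pytest.fixture(scope="session")
def ca1_like_swc(tmp_path_factory):
    """A small CA1-like SWC fixture with documented region counts:
    1 soma node, 3 axon, 4 basal, 6 apical (trunk+obliques)."""
    lines = ["# ca1-like fixture", "1 1 0 0 0 8.0 -1"]
    nid = 2
    # axon chain (3 nodes)
    parent = 1
    for k in range(3):
        lines.append(f"{nid} 2 0 {-20 * (k + 1)} 0 0.6 {parent}")
        parent = nid
        nid += 1
    # two basal branches of two nodes each
    for b in range(2):
        parent = 1
        for k in range(2):
            lines.append(
                f"{nid} 3 {30 * (k + 1) * (1 if b else -1)} 5 0 0.5 {parent}")
            parent = nid
            nid += 1
    # apical trunk (3 nodes, tapering) with one 3-node oblique
    parent = 1
    trunk_ids = []
    for k in range(3):
        r = 1.2 - 0.2 * k
        lines.append(f"{nid} 4 0 {40 * (k + 1)} 0 {r} {parent}")
        trunk_ids.append(nid)
        parent = nid
        nid += 1
    parent = trunk_ids[1]
    for k in range(3):
        lines.append(f"{nid} 4 {15 * (k + 1)} 80 0 0.4 {parent}")
        parent = nid
        nid += 1
    path = tmp_path_factory.mktemp("swc") / "ca1_like.swc"
    path.write_text("\n".join(lines) + "\n")
    return path


EXPECTED_CA1_REGION_COUNTS = {"soma": 1, "axon": 3, "basal": 4,
                              "apical_trunk": 3, "oblique": 3}


def make_trace(t, v, **meta):
    defaults = dict(amplitude=0.1, delay=0.0, duration=float(t[-1]),
                    protocol="synthetic")
    defaults.update(meta)
    return VoltageTrace(time=np.asarray(t, float),
                       voltage=np.asarray(v, float), meta=defaults)


def run_step(cell, amp, delay=200.0, duration=400.0, dt=0.025, post=200.0,
             **meta):
    cell.clear_stimuli()
    cell.inject_step_current("soma", amp, delay, duration)
    cfg = SimulationConfig(t_stop=delay + duration + post, dt=dt)
    res = simulate(cell, cfg, meta=dict(amplitude=amp, delay=delay,
                                        duration=duration,
                                        protocol="step", **meta))
    cell.clear_stimuli()
    return res.soma
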