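"""Neuron geometry: SWC reading, reduced species presets, path distances,
distance-dependent conductance distributions and synapse-site eligibility."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "CompartmentGraph",
    "DistributionRule",
    "SynapsePlacementRule",
    "read_swc",
    "write_swc",
    "build_reduced_morphology",
    "apply_distributions",
    "eligible_synapse_sites",
    "REGIONS",
]

REGIONS = ("soma", "axon", "basal", "apical_trunk", "oblique")

#: Region aliases accepted by distribution / placement rules.
_REGION_GROUPS = {
    "apical": ("apical_trunk", "oblique"),
    "dendrites": ("basal", "apical_trunk", "oblique"),
    "all": REGIONS,
}


def expand_regions(regions) -> set:
    out = set()
    for r in regions:
        out.update(_REGION_GROUPS.get(r, (r,)))
    unknown = out - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown regions: {sorted(unknown)}")
    return out


@dataclass
class Section:
    """An unbranched cable piece with linearly tapering diameter."""

    name: str
    region: str
    length: float           # um
    diam_prox: float        # um
    diam_dist: float        # um
    parent: "Section | None" = None
    parent_pos: float = 1.0  # attachment point on the parent, in [0, 1]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.length <= 0:
            raise ValueError(f"section {self.name}: length must be > 0")
        if self.diam_prox <= 0 or self.diam_dist <= 0:
            raise ValueError(f"section {self.name}: diameters must be > 0")

    def diam_at(self, pos: float) -> float:
        return self.diam_prox + (self.diam_dist - self.diam_prox) * pos


class Morphology:
    """A tree of sections rooted at the soma."""

    def __init__(self, sections):
        self.sections = list(sections)
        self._validate()

    def _validate(self) -> None:
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root section, got {len(roots)}")
        if roots[0].region != "soma":
            raise ValueError("root section must be the soma")
        self.root = roots[0]
        seen = set()
        order = [self.root]
        children = {id(s): [] for s in self.sections}
        for s in self.sections:
            if s.parent is not None:
                if id(s.parent) not in children:
                    raise ValueError(f"section {s.name}: parent not in morphology")
                children[id(s.parent)].append(s)
        stack = [self.root]
        seen.add(id(self.root))
        while stack:
            s = stack.pop()
            for c in children[id(s)]:
                if id(c) in seen:
                    raise ValueError("cycle detected in section tree")
                seen.add(id(c))
                stack.append(c)
        if len(seen) != len(self.sections):
            raise ValueError("section tree contains unreachable sections")
        self._children = children

    def children_of(self, sec: Section):
        return self._children[id(sec)]

    def path_distance(self, sec: Section, pos: float) -> float:
        """Path distance (um) from the soma centre to ``pos`` on ``sec``."""
        if sec is self.root:
            return abs(pos - 0.5) * sec.length
        d = pos * sec.length
        s = sec.parent
        p = sec.parent_pos
        while s is not self.root:
            d += p * s.length
            p = s.parent_pos
            s = s.parent
        # soma contribution measured from its centre
        d += abs(p - 0.5) * s.length
        return d

    def total_length(self, regions=None) -> float:
        regions = set(REGIONS) if regions is None else expand_regions(regions)
        return sum(s.length for s in self.sections if s.region in regions)

    def discretize(self, max_seg_um: float = 20.0) -> "CompartmentGraph":
        return CompartmentGraph(self, max_seg_um)


class CompartmentGraph:
    """Discretization of a morphology into cylindrical compartments.

    Each section is split into an odd number of segments of at most
    ``max_seg_um``; compartments are ordered so that every parent precedes
    its children (required by the tree solver).
    """

    def __init__(self, morphology: Morphology, max_seg_um: float = 20.0):
        self.morphology = morphology
        secs, parents = [], []
        # breadth-first for parent-before-child ordering
        queue = [morphology.root]
        order = []
        while queue:
            s = queue.pop(0)
            order.append(s)
            queue.extend(morphology.children_of(s))
        comp_of_sec_end = {}
        section_slices = {}
        region, length, diam, area, path, parent_idx, sec_name = (
            [], [], [], [], [], [], [])
        for s in order:
            nseg = max(1, int(math.ceil(s.length / max_seg_um)))
            if nseg % 2 == 0:
                nseg += 1
            start = len(region)
            for j in range(nseg):
                lo, hi = j / nseg, (j + 1) / nseg
                mid = (lo + hi) / 2
                dl = s.length / nseg
                d0, d1 = s.diam_at(lo), s.diam_at(hi)
                # lateral area of the frustum, in cm^2
                slant = math.sqrt(dl ** 2 + ((d1 - d0) / 2) ** 2)
                a = math.pi * (d0 + d1) / 2 * slant * 1e-8
                if j == 0:
                    if s.parent is None:
                        pidx = -1
                    else:
                        pidx = comp_of_sec_end[id(s.parent)]
                else:
                    pidx = len(region) - 1
                region.append(s.region)
                length.append(dl)
                diam.append(s.diam_at(mid))
                area.append(a)
                path.append(morphology.path_distance(s, mid))
                parent_idx.append(pidx)
                sec_name.append(s.name)
            section_slices[s.name] = slice(start, len(region))
            # children attach at the distal end compartment
            comp_of_sec_end[id(s)] = len(region) - 1
        self.region = np.array(region)
        self.length_um = np.array(length)
        self.diam_um = np.array(diam)
        self.area_cm2 = np.array(area)
        self.path_um = np.array(path)
        self.parent = np.array(parent_idx, dtype=np.int64)
        self.section_name = np.array(sec_name)
        self.section_slices = section_slices
        self.n = len(region)

    def axial_conductance(self, ra_ohm_cm: float) -> np.ndarray:
        """Absolute conductance (S) linking each compartment to its parent."""
        # half-cylinder resistances in ohms; lengths um -> cm, diam um -> cm
        r_half = (ra_ohm_cm * (self.length_um * 1e-4 / 2)
                  / (math.pi * (self.diam_um * 1e-4 / 2) ** 2))
        g = np.zeros(self.n)
        for i in range(1, self.n):
            p = self.parent[i]
            g[i] = 1.0 / (r_half[i] + r_half[p])
        return g

    def index_at(self, section_name: str, pos: float = 0.5) -> int:
        sl = self.section_slices[section_name]
        nseg = sl.stop - sl.start
        j = min(nseg - 1, int(pos * nseg))
        return sl.start + j

    @property
    def soma_index(self) -> int:
        return self.index_at(self.morphology.root.name, 0.5)


# ---------------------------------------------------------------------------
# SWC

_SWC_REGION = {1: "soma", 2: "axon", 3: "basal", 4: "apical_trunk"}
_REGION_SWC = {"soma": 1, "axon": 2, "basal": 3, "apical_trunk": 4, "oblique": 4}


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a morphology.

    SWC types 1/2/3/4 map to soma/axon/basal/apical; the apical trunk is the
    maximal-diameter path from the apical root, branches off it are obliques.
    """
    nodes = {}
    order = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        nid, typ = int(parts[0]), int(parts[1])
        x, y, z, r = (float(p) for p in parts[2:6])
        pid = int(parts[6])
        if r <= 0:
            raise ValueError(f"node {nid}: non-positive radius")
        if pid != -1 and pid not in nodes:
            raise ValueError(f"node {nid}: parent {pid} not yet defined")
        nodes[nid] = (typ, x, y, z, r, pid)
        order.append(nid)
    roots = [nid for nid in order if nodes[nid][5] == -1]
    if len(roots) != 1:
        raise ValueError(f"expected one root node, found {len(roots)}")
    root_id = roots[0]
    typ, x, y, z, r, _ = nodes[root_id]
    if typ != 1:
        raise ValueError("root node must be soma (type 1)")

    soma = Section("soma", "soma", length=2 * r, diam_prox=2 * r, diam_dist=2 * r)
    sections = [soma]
    sec_of_node = {root_id: soma}
    children = {nid: [] for nid in order}
    for nid in order:
        pid = nodes[nid][5]
        if pid != -1:
            children[pid].append(nid)

    for nid in order:
        if nid == root_id:
            continue
        typ, x, y, z, r, pid = nodes[nid]
        if typ == 1:
            # extra soma points are merged into the root section
            sec_of_node[nid] = soma
            continue
        region = _SWC_REGION.get(typ, "basal")
        pt, px, py, pz, pr, _ = nodes[pid]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            length = 1e-3
        parent_sec = sec_of_node[pid]
        sec = Section(f"n{nid}", region, length,
                      diam_prox=2 * pr if pt != 1 else 2 * r,
                      diam_dist=2 * r,
                      parent=parent_sec, parent_pos=1.0 if parent_sec is not soma else 0.5)
        sec_of_node[nid] = sec
        sections.append(sec)

    morph = Morphology(sections)
    _label_obliques(morph)
    return morph


def _label_obliques(morph: Morphology) -> None:
    """Trunk = maximal-diameter path from the apical root; side branches
    (and their subtrees) become obliques."""
    apical_roots = [s for s in morph.sections
                    if s.region == "apical_trunk"
                    and (s.parent is None or s.parent.region not in
                         ("apical_trunk", "oblique"))]
    on_trunk = set()
    for root in apical_roots:
        s = root
        while True:
            on_trunk.add(id(s))
            nxt = [c for c in morph.children_of(s)
                   if c.region == "apical_trunk"]
            if not nxt:
                break
            s = max(nxt, key=lambda c: c.diam_dist)
    for s in morph.sections:
        if s.region == "apical_trunk" and id(s) not in on_trunk:
            s.region = "oblique"


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as SWC with synthetic straight-line coordinates."""
    lines = ["# generated by ca1sim"]
    node_id = {}
    next_id = 1
    # direction per region for layout only
    direction = {"soma": (0, 1, 0), "axon": (0, -1, 0), "basal": (1, 0, 0),
                 "apical_trunk": (0, 1, 0), "oblique": (1, 1, 0)}
    coords = {}
    root = morph.root
    node_id[id(root)] = next_id
    coords[id(root)] = (0.0, 0.0, 0.0)
    lines.append(f"1 1 0.0 0.0 0.0 {root.diam_prox / 2:.6f} -1")
    next_id += 1
    queue = list(morph.children_of(root))
    while queue:
        s = queue.pop(0)
        px, py, pz = coords[id(s.parent)]
        dx, dy, dz = direction[s.region]
        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = px + dx / norm * s.length
        y = py + dy / norm * s.length
        z = pz + dz / norm * s.length
        nid = next_id
        next_id += 1
        node_id[id(s)] = nid
        coords[id(s)] = (x, y, z)
        lines.append(
            f"{nid} {_REGION_SWC[s.region]} {x:.6f} {y:.6f} {z:.6f} "
            f"{s.diam_dist / 2:.6f} {node_id[id(s.parent)]}"
        )
        queue.extend(morph.children_of(s))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reduced species presets

_GEOMETRY_PRESETS = {
    # mouse: smaller soma, thin trunk, short thin obliques -> high Rin
    "mouse": dict(
        soma_length=20.0, soma_diam=20.0,
        axon_length=100.0, axon_diam=1.0,
        trunk_length=350.0, trunk_diam_prox=1.8, trunk_diam_dist=0.8,
        n_obliques=5, oblique_length=120.0, oblique_diam=0.7,
        oblique_positions=(0.15, 0.30, 0.45, 0.60, 0.75),
        n_basal=4, basal_length=150.0, basal_diam=0.8,
    ),
    # rat: larger soma, thicker/longer trunk, more (short, thicker) obliques
    # -> low Rin and non-saturating distributed synaptic drive
    "rat": dict(
        soma_length=25.0, soma_diam=25.0,
        axon_length=100.0, axon_diam=1.5,
        trunk_length=400.0, trunk_diam_prox=3.0, trunk_diam_dist=1.4,
        n_obliques=16, oblique_length=50.0, oblique_diam=1.1,
        oblique_positions=(0.06, 0.112, 0.164, 0.216, 0.268, 0.32, 0.372,
                           0.424, 0.476, 0.529, 0.581, 0.633, 0.685, 0.737,
                           0.789, 0.85),
        n_basal=5, basal_length=180.0, basal_diam=1.0,
    ),
}


def build_reduced_morphology(spec) -> Morphology:
    """Reduced CA1-like geometry: soma + axon + tapering apical trunk with
    oblique side branches + basal tree.

    ``spec`` is a species name (``mouse``/``rat``) or an explicit geometry
    mapping with the keys of the presets.
    """
    if isinstance(spec, str):
        try:
            g = dict(_GEOMETRY_PRESETS[spec])
        except KeyError:
            raise ValueError(f"unknown geometry preset {spec!r}") from None
    else:
        g = dict(spec)
    for key, val in g.items():
        if key.startswith(("soma", "axon", "trunk", "oblique_l", "oblique_d",
                           "basal_l", "basal_d")) and not np.all(
                np.asarray(val, dtype=float) > 0):
            raise ValueError(f"geometry parameter {key} must be positive")
    soma = Section("soma", "soma", g["soma_length"], g["soma_diam"],
                   g["soma_diam"])
    sections = [soma]
    sections.append(Section("axon", "axon", g["axon_length"], g["axon_diam"],
                            g["axon_diam"], parent=soma, parent_pos=0.0))
    trunk = Section("apical_trunk", "apical_trunk", g["trunk_length"],
                    g["trunk_diam_prox"], g["trunk_diam_dist"],
                    parent=soma, parent_pos=1.0)
    sections.append(trunk)
    for i, pos in enumerate(g["oblique_positions"][: g["n_obliques"]]):
        sections.append(Section(f"oblique{i}", "oblique", g["oblique_length"],
                                g["oblique_diam"], g["oblique_diam"],
                                parent=trunk, parent_pos=pos))
    for i in range(g["n_basal"]):
        sections.append(Section(f"basal{i}", "basal", g["basal_length"],
                                g["basal_diam"], g["basal_diam"],
                                parent=soma, parent_pos=0.5))
    return Morphology(sections)


# ---------------------------------------------------------------------------
# Conductance distributions

@dataclass
class DistributionRule:
    """How one channel's density varies with path distance within regions.

    Profiles (``x`` = path distance to the soma centre, um):

    - ``uniform``:  d(x) = base
    - ``linear_with_distance``: d(x) = base + slope * x, or, with the
      relative parameters ``fold``/``fold_at``, base * (1 + (fold-1)*x/fold_at)
    - ``sigmoidal_with_distance``:
      d(x) = base * (1 + (fold - 1) / (1 + exp((midpoint - x)/steepness)))

    ``base`` defaults to the per-region peak conductance supplied to
    :func:`apply_distributions`, so a single optimizable scalar scales the
    whole profile.  Densities are clamped to ``[clamp_min, clamp_max]``.
    """

    channel: str
    regions: tuple
    profile: str = "uniform"
    parameters: dict = field(default_factory=dict)
    clamp_min: float = 0.0
    clamp_max: float = math.inf

    def __post_init__(self) -> None:
        if self.profile not in ("uniform", "linear_with_distance",
                                "sigmoidal_with_distance"):
            raise ValueError(f"unknown profile {self.profile!r}")
        self.regions = tuple(self.regions)
        expand_regions(self.regions)

    def density(self, base: float, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.parameters
        b = p.get("base", base)
        if self.profile == "uniform":
            d = np.full_like(x, b)
        elif self.profile == "linear_with_distance":
            if "fold" in p:
                d = b * (1.0 + (p["fold"] - 1.0) * x / p["fold_at"])
            else:
                d = b + p["slope"] * x
        else:
            d = b * (1.0 + (p["fold"] - 1.0)
                     / (1.0 + np.exp((p["midpoint"] - x) / p["steepness"])))
        return np.clip(d, self.clamp_min, self.clamp_max)


@dataclass
class SynapsePlacementRule:
    """Eligibility of a dendritic site for an excitatory synapse."""

    max_diameter: float          # um
    max_path_distance: float     # um
    eligible_regions: tuple = ("oblique", "apical_trunk")

    def __post_init__(self) -> None:
        if self.max_diameter <= 0 or self.max_path_distance <= 0:
            raise ValueError("placement thresholds must be > 0")
        self.eligible_regions = tuple(expand_regions(self.eligible_regions))


#: Species placement presets for the Schaffer-collateral pathway.
PLACEMENT_PRESETS = {
    "mouse": SynapsePlacementRule(max_diameter=1.0, max_path_distance=330.0),
    "rat": SynapsePlacementRule(max_diameter=1.2, max_path_distance=360.0),
}


def apply_distributions(graph, rules, region_gbars,
                        max_seg_um: float = 20.0) -> dict:
    """Per-compartment density map {channel: array of S/cm^2}.

    ``graph`` is a :class:`CompartmentGraph` (a :class:`Morphology` is
    discretized on the fly).  ``region_gbars`` maps channel -> {region: gbar};
    channels without an explicit rule are uniform within their regions.
    """
    if isinstance(graph, Morphology):
        graph = graph.discretize(max_seg_um)
    rules_by_channel = {}
    for r in rules:
        rules_by_channel.setdefault(r.channel, []).append(r)
    for ch in rules_by_channel:
        if ch not in region_gbars:
            raise ValueError(f"rule references unknown channel {ch!r}")
    out = {}
    for ch, per_region in region_gbars.items():
        dens = np.zeros(graph.n)
        expanded = {}
        for reg, gbar in per_region.items():
            for r in expand_regions([reg]):
                expanded[r] = gbar
        for reg, gbar in expanded.items():
            mask = graph.region == reg
            if not mask.any():
                continue
            rule = next(
                (r for r in rules_by_channel.get(ch, ())
                 if reg in expand_regions(r.regions)), None)
            if rule is None:
                dens[mask] = gbar
            else:
                dens[mask] = rule.density(gbar, graph.path_um[mask])
        if np.any(dens < 0):
            raise AssertionError("negative density after clamping")
        out[ch] = dens
    return out


def eligible_synapse_sites(graph, rule: SynapsePlacementRule, n: int,
                           seed: int, max_seg_um: float = 20.0):
    """Draw ``n`` synapse sites (compartment indices) satisfying ``rule``.

    Sites are drawn uniformly over eligible compartments, with replacement;
    reproducible under ``seed``.
    """
    if isinstance(graph, Morphology):
        graph = graph.discretize(max_seg_um)
    mask = ((graph.diam_um < rule.max_diameter)
            & (graph.path_um <= rule.max_path_distance)
            & np.isin(graph.region, list(rule.eligible_regions)))
    eligible = np.flatnonzero(mask)
    if eligible.size == 0:
        raise ValueError("no compartments satisfy the placement rule")
    rng = np.random.default_rng(seed)
    return [int(i) for i in rng.choice(eligible, size=n, replace=True)]
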