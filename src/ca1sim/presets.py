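"""Shipped species presets: conductance densities, distance rules, passive
properties and cell builders for the reduced mouse-like and rat-like models.

Densities are design defaults tuned so that the reduced cells rest near
-70 mV, fire regular trains over the positive protocol range, and show an
Ih sag for hyperpolarizing steps.  The optimizer treats all of them as free
parameters, so they act as generator ground truth, not as claims about
biological densities.
"""

from __future__ import annotations

import copy

from .channels import default_channel_library
from .morphology import (DistributionRule, build_reduced_morphology,
                         apply_distributions)
from .simulator import Cell, assemble

__all__ = [
    "default_distribution_rules",
    "region_gbar_preset",
    "passive_preset",
    "build_cell",
]


def default_distribution_rules():
    """Ih and KAd increase linearly 6-fold over 350 um; KD is sigmoidal."""
    return [
        DistributionRule("Ih", ("apical",), "linear_with_distance",
                         {"fold": 6.0, "fold_at": 350.0}),
        DistributionRule("KAd", ("dendrites",), "linear_with_distance",
                         {"fold": 6.0, "fold_at": 350.0}),
        DistributionRule("KD", ("dendrites",), "sigmoidal_with_distance",
                         {"fold": 5.0, "midpoint": 150.0, "steepness": 30.0}),
    ]


# peak conductances, S/cm^2, per channel and region
_GBARS = {
    "mouse": {
        "Nax": {"axon": 0.4},
        "Na3": {"soma": 0.2, "basal": 0.02, "apical": 0.06},
        "KDR": {"soma": 0.008, "axon": 0.016, "basal": 0.002, "apical": 0.002},
        "KAp": {"soma": 0.004, "axon": 0.008},
        "KAd": {"basal": 0.0015, "apical": 0.0015},
        "KM": {"soma": 5e-4, "axon": 5e-4},
        "KD": {"basal": 1e-4, "apical": 1e-4},
        "CaN": {"soma": 5e-4, "basal": 1e-4, "apical": 1e-4},
        "CaL": {"soma": 5e-4, "basal": 1e-4, "apical": 1e-4},
        "CaT": {"soma": 1e-4, "basal": 2e-4, "apical": 2e-4},
        "KCa": {"soma": 2e-5, "basal": 1e-5, "apical": 1e-5},
        "Cagk": {"soma": 1e-4, "basal": 5e-5, "apical": 5e-5},
        "Ih": {"soma": 2e-5, "basal": 2e-5, "apical": 2e-5},
    },
    "rat": {
        "Nax": {"axon": 0.4},
        "Na3": {"soma": 0.25, "basal": 0.02, "apical": 0.04},
        "KDR": {"soma": 0.008, "axon": 0.008, "basal": 0.002, "apical": 0.002},
        "KAp": {"soma": 0.004, "axon": 0.008},
        "KAd": {"basal": 0.0015, "apical": 0.0015},
        "KM": {"soma": 5e-4, "axon": 5e-4},
        "KD": {"basal": 1e-4, "apical": 1e-4},
        "CaN": {"soma": 5e-4, "basal": 1e-4, "apical": 2e-3},
        "CaL": {"soma": 5e-4, "basal": 1e-4, "apical": 1e-4},
        "CaT": {"soma": 1e-4, "basal": 2e-4, "apical": 2e-4},
        "KCa": {"soma": 2e-4, "basal": 5e-5, "apical": 5e-5},
        "Cagk": {"soma": 2e-4, "basal": 5e-5, "apical": 5e-4},
        "Ih": {"soma": 2e-5, "basal": 2e-5, "apical": 2e-5},
    },
}

_PASSIVE = {
    "mouse": dict(ra=150.0, cm=1.0, g_pas=6.0e-5, e_pas=-62.0),
    "rat": dict(ra=150.0, cm=1.0, g_pas=8.0e-5, e_pas=-62.0),
}


def region_gbar_preset(species: str) -> dict:
    return copy.deepcopy(_GBARS[species])


def passive_preset(species: str) -> dict:
    return dict(_PASSIVE[species])


def build_cell(species: str, region_gbars=None, passive=None,
               max_seg_um: float = 20.0, morphology=None) -> Cell:
    """Assemble the reduced species cell, optionally overriding parameters."""
    morph = morphology or build_reduced_morphology(species)
    graph = morph.discretize(max_seg_um)
    gbars = region_gbars or region_gbar_preset(species)
    pas = dict(passive_preset(species))
    if passive:
        pas.update(passive)
    density = apply_distributions(graph, default_distribution_rules(), gbars)
    channels = default_channel_library(species)
    return assemble(graph, density, channels, **pas)
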