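"""Bundled parameter sets and ready-made scenarios.

Values are literature-standard electrophysiological constants expressed in
the resistivity formulation used throughout the package (per-area constants
are obtained by dividing by the membrane thickness h; see
:mod:`cabletree.membrane`).
"""

from __future__ import annotations

import numpy as np

from . import solvers
from .membrane import ElectricalParams
from .morphology import NeuriteTree, build_myelinated_axon

__all__ = [
    "classic_squid",
    "mammalian_node_params",
    "myelinated_axon_fixture",
    "probe_near",
    "PARAM_PRESETS",
]

#: reference membrane thickness used to convert per-area constants (m)
H_MEMBRANE = 1.0e-8


def classic_squid(h: float = H_MEMBRANE) -> ElectricalParams:
    """The classic squid-axon HH parameter set, resistivity form.

    Per-area values: C 1.0 µF/cm², Ḡ_Na 120 mS/cm², Ḡ_K 36 mS/cm²,
    G_L 0.3 mS/cm²; axoplasm resistivity 35.4 Ω·cm; V_rest −65 mV,
    E_Na = V_rest + 115 mV, E_K = V_rest − 12 mV.  The passive membrane
    resistivity matches the leak (R_m·area = 1/G_L,area = 1/3 Ω·m²); the
    myelin sheath, when present, reuses the membrane constants per layer.
    E_L is derived from the rest condition on first use.
    """
    return ElectricalParams(
        rho_a=0.354,              # 35.4 Ω·cm
        rho_m=(1.0 / 3.0) / h,    # R_m·area = 1/3 Ω·m²
        C_m=0.01 * h,             # 0.01 F/m² per area
        V_rest=-0.065,
        rho_my=(1.0 / 3.0) / h,
        C_my=0.01 * h,
        Gbar_Na=1200.0 * h,       # 120 mS/cm² per area
        Gbar_K=360.0 * h,         # 36 mS/cm² per area
        G_L=3.0 * h,              # 0.3 mS/cm² per area
        E_Na=-0.065 + 0.115,
        E_K=-0.065 - 0.012,
    )


def mammalian_node_params(h: float = H_MEMBRANE,
                          node_density_factor: float = 10.0) -> ElectricalParams:
    """Squid kinetics with node-of-Ranvier channel densities.

    Nodes of Ranvier carry an order of magnitude higher voltage-gated
    channel density than unmyelinated squid membrane; the factor (default
    10×) scales Ḡ_Na and Ḡ_K only.
    """
    import dataclasses
    p = classic_squid(h)
    return dataclasses.replace(p,
                               Gbar_Na=p.Gbar_Na * node_density_factor,
                               Gbar_K=p.Gbar_K * node_density_factor)


PARAM_PRESETS = {
    "classic_squid": classic_squid,
    "mammalian_node": mammalian_node_params,
}


def probe_near(tree: NeuriteTree, x: float, mm: str | None = None) -> int:
    """Element index whose centre arc distance is nearest to x (ties -> lower
    index), optionally restricted to one membrane model."""
    pos = tree.arrays().axial_pos
    if mm is None:
        return int(np.argmin(np.abs(pos - x)))  # argmin takes the first minimum
    cand = np.array([e.index for e in tree.elements if e.mm == mm])
    if cand.size == 0:
        raise ValueError(f"no {mm} elements in the tree")
    return int(cand[np.argmin(np.abs(pos[cand] - x))])


def myelinated_axon_fixture(n_nodes: int = 50,
                            len_NR: float = 2e-6, dx_NR: float = 1e-6,
                            len_IR: float = 200e-6, dx_IR: float = 10e-6,
                            d: float = 1e-6, n_my: int = 20,
                            h_my: float = 1e-8,
                            stim_amplitude: float = 5e-10,
                            stim_duration: float = 1e-4):
    """The standard ~10 mm myelinated-axon scenario.

    50 nodes of Ranvier (2 µm, HH, squid kinetics at 10× nodal density)
    alternating with 49 internodes (200 µm, 20 myelin layers) on a 1 µm
    fibre: total length 9.9 mm.  A 0.5 nA, 0.1 ms rectangular pulse enters
    the first node.  Returns (tree, params, stimulus, probes) where probes
    are [proximal node, mid node, distal node, distal mid-internode].
    """
    tree = build_myelinated_axon(n_nodes=n_nodes, len_NR=len_NR, dx_NR=dx_NR,
                                 len_IR=len_IR, dx_IR=dx_IR, d=d,
                                 h=H_MEMBRANE, n_my=n_my, h_my=h_my)
    params = mammalian_node_params()
    stimulus = solvers.StimulusProtocol(
        [(1, solvers.RectPulse(0.0, stim_duration, stim_amplitude))])
    total = tree.total_length
    node_pitch = len_NR + len_IR
    probes = [
        probe_near(tree, 2 * node_pitch, mm="HH"),             # proximal node
        probe_near(tree, total / 2, mm="HH"),                  # mid node
        probe_near(tree, total - 3 * node_pitch, mm="HH"),     # distal node
        probe_near(tree, total - 2.5 * node_pitch, mm="CT"),   # distal mid-IR
    ]
    return tree, params, stimulus, probes
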