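"""Mechanical loading of a neurite: strain-driven geometry change and the
channel-alteration hook.

A macroscopic axial strain (with its strain rate) is converted to a
microscopic axial neurite strain by a pluggable *transfer function*
(identity by default; tissue-to-cell strain transfer models can be
registered).  The microscopic strain ε rescales every element
quasi-statically before time stepping:

    Δx = Δx₀ (1 + ε),        d = d₀ / √(1 + ε)

so the volume proxy d²Δx is exactly conserved (axial incompressible
stretch).  Stretch-induced channel damage (e.g. the sodium-current
left-shift) is exposed only as a hook: a :class:`ChannelAlteration` overlay
that scales conductances, offsets reversal potentials, or shifts the
potential seen by the gating rate constants on selected HH elements.  The
leak reversal E_L is *not* recomputed under loading (ion homeostasis is
assumed to hold it fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .morphology import HH, NeuriteTree

__all__ = [
    "MechanicalLoading",
    "ChannelAlteration",
    "register_transfer",
    "get_transfer",
    "micro_strain",
    "apply_strain",
    "apply_channel_alteration",
    "apply_loading",
]

TransferFn = Callable[[float, float], float]

_TRANSFERS: dict[str, TransferFn] = {}


def register_transfer(name: str, fn: TransferFn) -> None:
    """Register a macroscopic→microscopic strain transfer function
    ``fn(macro_strain, strain_rate) -> micro_strain``."""
    _TRANSFERS[name] = fn


def get_transfer(name: str) -> TransferFn:
    try:
        return _TRANSFERS[name]
    except KeyError:
        raise ValueError(
            f"unknown strain transfer {name!r}; registered: "
            f"{sorted(_TRANSFERS)}") from None


register_transfer("identity", lambda strain, rate: strain)


@dataclass(frozen=True)
class ChannelAlteration:
    """Per-element modifier of HH channel properties (identity by default).

    ``rate_v_shift`` (V) shifts the potential seen by the gating rate
    constants (positive = left-shift style hyperpolarizing shift of the
    kinetics); conductance scales multiply the maximal conductivities;
    dE_Na/dE_K offset the reversal potentials.
    """

    gbar_na_scale: float = 1.0
    gbar_k_scale: float = 1.0
    g_l_scale: float = 1.0
    dE_Na: float = 0.0
    dE_K: float = 0.0
    rate_v_shift: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (self.gbar_na_scale == 1.0 and self.gbar_k_scale == 1.0
                and self.g_l_scale == 1.0 and self.dE_Na == 0.0
                and self.dE_K == 0.0 and self.rate_v_shift == 0.0)


@dataclass
class MechanicalLoading:
    """One quasi-static mechanical insult.

    ``macro_strain`` is the macroscopic axial engineering strain (> −1);
    ``strain_rate`` (1/s) is carried through to the transfer function and
    alteration hooks (the default identity transfer ignores it).
    ``channel_alteration`` maps HH element index -> :class:`ChannelAlteration`
    (None = geometry-only loading).
    """

    macro_strain: float
    strain_rate: float = 0.0
    transfer: str = "identity"
    channel_alteration: dict[int, ChannelAlteration] | None = None

    def __post_init__(self):
        if self.macro_strain <= -1.0:
            raise ValueError("macro_strain must be > -1")


def micro_strain(load: MechanicalLoading) -> float:
    """Microscopic axial strain ε = transfer(macro_strain, strain_rate)."""
    eps = float(get_transfer(load.transfer)(load.macro_strain, load.strain_rate))
    if eps <= -1.0:
        raise ValueError(f"transfer produced micro strain {eps} <= -1")
    return eps


def apply_strain(tree: NeuriteTree, eps: float) -> NeuriteTree:
    """Return a strained copy of the tree: Δx = Δx₀(1+ε), d = d₀/√(1+ε).

    Reference values are untouched, so applying the inverse strain recovers
    the reference geometry; d²Δx = d₀²Δx₀ holds exactly.
    """
    if eps <= -1.0:
        raise ValueError("strain must be > -1")
    stretch = 1.0 + eps
    new = tree.copy()
    for e in new.elements:
        e.dx = e.dx0 * stretch
        e.d = e.d0 / stretch**0.5
    # recompute centre arc distances
    for e in new.elements:
        if e.index == 0:
            e.axial_pos = e.dx / 2.0
        else:
            p = new.elements[e.pa]
            e.axial_pos = p.axial_pos + (p.dx + e.dx) / 2.0
    new.invalidate()
    return new


def apply_channel_alteration(tree: NeuriteTree, alteration: ChannelAlteration,
                             elements=None) -> dict[int, ChannelAlteration]:
    """Build a per-element parameter overlay applying ``alteration`` to the
    given HH elements (default: all HH elements).

    The overlay is consumed by the solver assembly; an identity alteration
    produces a simulation bit-identical to the unaltered run.  Raises
    ``ValueError`` if any targeted element is not HH.
    """
    if elements is None:
        elements = [e.index for e in tree.elements if e.mm == HH]
    overlay: dict[int, ChannelAlteration] = {}
    for idx in elements:
        idx = int(idx)
        if not (0 <= idx < len(tree)) or tree[idx].mm != HH:
            raise ValueError(f"channel alteration targets non-HH element {idx}")
        overlay[idx] = alteration
    return overlay


def apply_loading(tree: NeuriteTree, load: MechanicalLoading):
    """Strain the geometry and validate the channel overlay.

    Returns ``(strained_tree, overlay)`` ready for the solver assembly.
    """
    eps = micro_strain(load)
    strained = apply_strain(tree, eps)
    overlay = None
    if load.channel_alteration:
        for idx in load.channel_alteration:
            if not (0 <= int(idx) < len(tree)) or tree[int(idx)].mm != HH:
                raise ValueError(
                    f"channel alteration targets non-HH element {idx}")
        overlay = dict(load.channel_alteration)
    return strained, overlay
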