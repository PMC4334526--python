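"""Electrical membrane models: lumped circuit quantities and HH kinetics.

Two membrane models are supported per element.  Passive cable theory (CT)
elements carry a constant leak; active Hodgkin-Huxley (HH) elements add
voltage-gated Na and K conductances governed by the gating variables m, h, n.

Geometry-derived quantities follow a resistivity formulation: the membrane
is a shell of thickness ``h`` and the myelin a stack of ``n_my`` concentric
shells of thickness ``h_my``, so capacitances combine in series and
resistances add.  Per-unit-length ("hatted") quantities are defined so that
for an element of length dx:

* axial resistance        r_a  = r̂_a · dx,      r̂_a = 4 ρ_a / (π d²)
* membrane capacitance    c_mm = ĉ_m · dx
* membrane resistance     r_m  = r̂_m / dx
* channel conductance     g    = ĝ · dx,        ĝ = π d G / h

Everything is SI (V, s, m, Ω, S, F) except the HH rate constants, which are
evaluated in the classic mV/ms convention and converted at the boundary.

The membrane current of an element is ``i = c_mm dV/dt + W V + K`` with the
lumped coefficients ``(W, K)``: for CT, ``W = −1/r_m``, ``K = V_rest/r_m``;
for HH, ``W = −(g_Na + g_K + g_L)``, ``K = g_Na E_Na + g_K E_K + g_L E_L``.
The leak reversal E_L is chosen once so that the total ionic current
vanishes at V_rest with gates at steady state, and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElectricalParams",
    "GatingState",
    "axial_resistance_per_length",
    "myelin_layer_diameter",
    "capacitance_per_length",
    "membrane_resistance_times_length",
    "rate_constants",
    "gate_steady_state",
    "gate_step",
    "channel_conductances",
    "leak_reversal",
    "coefficients_WK",
    "pde_coefficients",
]

_MS = 1e3   # s  -> ms rate conversion factor (1/ms -> 1/s is *1e3)
_MV = 1e3   # V  -> mV


@dataclass(frozen=True)
class ElectricalParams:
    """Circuit constants of the membrane models.

    Units: resistivities Ω·m; C_m, C_my are electric constants in F/m
    (capacitance per area = C/thickness, a parallel-plate/permittivity-style
    constant); conductivities Ḡ_Na, Ḡ_K, G_L in S/m (conductance per area =
    G/h); potentials in V.

    ``alpha_h_scale`` selects the α_h prefactor of the HH inactivation gate
    in ms⁻¹ (classic value 0.07).
    """

    rho_a: float           # axial resistivity of the cytoplasm (Ω·m)
    rho_m: float           # transmembrane resistivity (Ω·m)
    C_m: float             # membrane electric constant (F/m)
    V_rest: float          # resting potential (V)
    rho_my: float = 0.0    # trans-sheath (myelin) resistivity (Ω·m)
    C_my: float = 0.0      # myelin electric constant (F/m)
    Gbar_Na: float = 0.0   # max Na conductivity (S/m)
    Gbar_K: float = 0.0    # max K conductivity (S/m)
    G_L: float = 0.0       # leak conductivity (S/m)
    E_Na: float = 0.0      # Na reversal potential (V)
    E_K: float = 0.0       # K reversal potential (V)
    E_L: float | None = None  # leak reversal (V); None -> derive at rest
    alpha_h_scale: float = 0.07

    def __post_init__(self):
        for name in ("rho_a", "rho_m", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rho_my", "C_my", "Gbar_Na", "Gbar_K", "G_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_leak_reversal(self) -> "ElectricalParams":
        """Return a copy with E_L resolved via :func:`leak_reversal`."""
        if self.E_L is not None:
            return self
        return replace(self, E_L=leak_reversal(self))


@dataclass
class GatingState:
    """HH activation (m, n) and inactivation (h_gate) variables, each in
    [0, 1]; scalar or per-element numpy arrays."""

    m: np.ndarray | float
    h_gate: np.ndarray | float
    n: np.ndarray | float

    def copy(self) -> "GatingState":
        return GatingState(np.array(self.m, float, copy=True),
                           np.array(self.h_gate, float, copy=True),
                           np.array(self.n, float, copy=True))


# ----------------------------------------------------------------------
# Geometry-lumped quantities
# ----------------------------------------------------------------------

def axial_resistance_per_length(rho_a: float, d) -> float | np.ndarray:
    """r̂_a = 4 ρ_a / (π d²)  (Ω/m)."""
    if rho_a <= 0 or np.any(np.asarray(d) <= 0):
        raise ValueError("rho_a and d must be > 0")
    return 4.0 * rho_a / (np.pi * np.asarray(d, float) ** 2)


def myelin_layer_diameter(d, h, h_my, k):
    """Diameter of myelin layer k ≥ 1: d + 2h + 2(k−1)·h_my."""
    if np.any(np.asarray(k) < 1):
        raise ValueError("layer index k must be >= 1")
    return d + 2.0 * h + 2.0 * (np.asarray(k) - 1) * h_my


def capacitance_per_length(d, h, C_m, n_my=0, h_my=0.0, C_my=0.0):
    """ĉ_m (F/m): series combination of the membrane shell capacitance and
    the ``n_my`` myelin layer capacitances, all per unit length.

    ĉ_m = [ h/(C_m π d) + Σ_{k=1..n_my} h_my/(C_my π d_my^k) ]⁻¹ ; the myelin
    sum is discarded for bare membrane (n_my = 0).
    """
    d = np.asarray(d, float)
    inv = h / (C_m * np.pi * d)
    n_my = int(n_my)
    if n_my > 0:
        if C_my <= 0 or h_my <= 0:
            raise ValueError("myelinated element needs C_my > 0 and h_my > 0")
        ks = np.arange(1, n_my + 1)
        dmy = myelin_layer_diameter(d[..., None] if d.ndim else d, h, h_my, ks)
        inv = inv + np.sum(h_my / (C_my * np.pi * dmy), axis=-1)
    return 1.0 / inv


def membrane_resistance_times_length(d, h, rho_m, n_my=0, h_my=0.0, rho_my=0.0):
    """r̂_m (Ω·m): membrane shell resistance plus myelin layer resistances in
    series, each × unit length.

    r̂_m = ρ_m h/(π d) + Σ_{k=1..n_my} ρ_my h_my/(π d_my^k)
    """
    d = np.asarray(d, float)
    r = rho_m * h / (np.pi * d)
    n_my = int(n_my)
    if n_my > 0:
        if rho_my <= 0 or h_my <= 0:
            raise ValueError("myelinated element needs rho_my > 0 and h_my > 0")
        ks = np.arange(1, n_my + 1)
        dmy = myelin_layer_diameter(d[..., None] if d.ndim else d, h, h_my, ks)
        r = r + np.sum(rho_my * h_my / (np.pi * dmy), axis=-1)
    return r


# ----------------------------------------------------------------------
# HH gating kinetics (classic mV/ms convention)
# ----------------------------------------------------------------------

def _xexprel(x):
    """x / (exp(x) − 1) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))
    return out


def rate_constants(V, V_rest, alpha_h_scale: float = 0.07):
    """HH rate constants (α_m, β_m, α_h, β_h, α_n, β_n), each in ms⁻¹.

    ``V`` and ``V_rest`` are in volts; internally v = (V − V_rest) in mV:

    * α_m = 0.1 (25−v) / (exp((25−v)/10) − 1)     β_m = 4 exp(−v/18)
    * α_h = a_h exp(−v/20)                        β_h = 1/(exp((30−v)/10)+1)
    * α_n = 0.01 (10−v) / (exp((10−v)/10) − 1)    β_n = 0.125 exp(−v/80)

    The removable singularities of α_m (v = 25) and α_n (v = 10) are
    evaluated by their limits.
    """
    v = (np.asarray(V, float) - V_rest) * _MV
    alpha_m = _xexprel((25.0 - v) / 10.0)
    beta_m = 4.0 * np.exp(-v / 18.0)
    alpha_h = alpha_h_scale * np.exp(-v / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
    alpha_n = 0.1 * _xexprel((10.0 - v) / 10.0)
    beta_n = 0.125 * np.exp(-v / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def gate_steady_state(V, V_rest, alpha_h_scale: float = 0.07) -> GatingState:
    """Fixed point x_∞ = α/(α+β) of each gating ODE at clamped V."""
    am, bm, ah, bh, an, bn = rate_constants(V, V_rest, alpha_h_scale)
    return GatingState(m=am / (am + bm), h_gate=ah / (ah + bh), n=an / (an + bn))


def gate_step(state: GatingState, V, dt: float, V_rest,
              alpha_h_scale: float = 0.07, v_shift=0.0) -> GatingState:
    """Forward-Euler update of the gating ODE dx/dt = α(V)(1−x) − β(V)x.

    ``dt`` is in seconds (converted to ms for the rates); gates are clamped
    to [0, 1] after the update.  ``v_shift`` (V) shifts the potential seen by
    the rate constants (channel-alteration hook; 0 = healthy).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    Veff = np.asarray(V, float) - v_shift
    am, bm, ah, bh, an, bn = rate_constants(Veff, V_rest, alpha_h_scale)
    dt_ms = dt * _MS

    def upd(x, a, b):
        # α(1−x) − βx  ==  α − (α+β)x
        x1 = x + dt_ms * (a - (a + b) * x)
        return np.minimum(np.maximum(x1, 0.0), 1.0)

    return GatingState(m=upd(state.m, am, bm),
                       h_gate=upd(state.h_gate, ah, bh),
                       n=upd(state.n, an, bn))


def channel_conductances(state: GatingState, Gbar_Na, Gbar_K):
    """(G_Na, G_K) = (Ḡ_Na m³ h, Ḡ_K n⁴) in S/m."""
    g_na = Gbar_Na * np.asarray(state.m) ** 3 * np.asarray(state.h_gate)
    g_k = Gbar_K * np.asarray(state.n) ** 4
    return g_na, g_k


def leak_reversal(params: ElectricalParams) -> float:
    """Leak reversal potential E_L fixing V = V_rest as the rest state.

    E_L = (1 + G*_Na/G_L + G*_K/G_L) V_rest − (G*_Na E_Na + G*_K E_K)/G_L
    with G*_Na, G*_K the channel conductivities at rest (gates at steady
    state).  The value is computed once and frozen for the whole simulation.
    """
    if params.G_L <= 0:
        raise ValueError("G_L must be > 0 to define the leak reversal")
    ss = gate_steady_state(params.V_rest, params.V_rest, params.alpha_h_scale)
    g_na, g_k = channel_conductances(ss, params.Gbar_Na, params.Gbar_K)
    gl = params.G_L
    return float((1.0 + g_na / gl + g_k / gl) * params.V_rest
                 - (g_na * params.E_Na + g_k * params.E_K) / gl)


# ----------------------------------------------------------------------
# Per-element lumped coefficients
# ----------------------------------------------------------------------

def coefficients_WK(element, params: ElectricalParams,
                    state: GatingState | None = None):
    """Lumped membrane coefficients (W, K) of one element (W in S, K in A).

    CT:  W = −1/r_m, K = V_rest/r_m with r_m = r̂_m/Δx.
    HH:  W = −(g_Na + g_K + g_L), K = g_Na E_Na + g_K E_K + g_L E_L with each
    g = ĝ·Δx = π d G Δx / h; requires the element's gating ``state`` and a
    resolved E_L.
    """
    if element.mm == "CT":
        r_hat_m = membrane_resistance_times_length(
            element.d, element.h, params.rho_m, element.n_my, element.h_my,
            params.rho_my)
        r_m = r_hat_m / element.dx
        return -1.0 / r_m, params.V_rest / r_m
    if state is None:
        raise ValueError("HH element requires a gating state")
    e_l = params.E_L if params.E_L is not None else leak_reversal(params)
    g_na_cond, g_k_cond = channel_conductances(state, params.Gbar_Na, params.Gbar_K)
    geom = np.pi * element.d * element.dx / element.h
    g_na, g_k, g_l = geom * g_na_cond, geom * g_k_cond, geom * params.G_L
    W = -(g_na + g_k + g_l)
    K = g_na * params.E_Na + g_k * params.E_K + g_l * e_l
    return float(W), float(K)


def pde_coefficients(element, params: ElectricalParams,
                     state: GatingState | None = None):
    """(A, B, C, D) of the PDE form  A ∂²V/∂x² = B ∂V/∂t + C V + D.

    A = π d²/(4 ρ_a); B = ĉ_m; C and D are the per-unit-length counterparts
    of the lumped (W, K): C = −W/Δx, D = −K/Δx.
    """
    A = np.pi * element.d**2 / (4.0 * params.rho_a)
    B = capacitance_per_length(element.d, element.h, params.C_m,
                               element.n_my, element.h_my, params.C_my)
    W, K = coefficients_WK(element, params, state)
    return float(A), float(B), float(-W / element.dx), float(-K / element.dx)
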