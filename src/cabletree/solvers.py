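"""Explicit and implicit finite-difference solvers on the element tree.

Both schemes advance the compartmental form of the cable/HH equations.  For
element i with lumped capacitance c_i = ĉ_m Δx, membrane coefficients
(W_i, K_i) and axial link conductances g to its neighbours, the membrane
current balance (Kirchhoff's first law on the tree) reads

    c_i dV_i/dt = W_i V_i + K_i + Σ_links g (V_neigh − V_i) + i_input .

The explicit scheme is forward Euler on this system; its stability limit is
the critical time step Δt_c derived from a von Neumann analysis of the
uniform unbranched chain, Δt_c = min_i 2B_i / (C_i + 4 A_i/Δx_i²), checked
against a spectral-radius oracle on the assembled update matrix.  The
implicit scheme is backward Euler with the membrane coefficients frozen at
Vⁿ (semi-implicit linearization), yielding one quasi-tridiagonal linear
system per step: tridiagonal bands plus one (k,l)/(l,k) off-diagonal entry
pair per branching, stored in compressed sparse row form.

Sealed ends are enforced by ghost equalities V_0 = V_1 at the root and
V_terminal = V_parent at the tips: applied by direct overwrite after each
explicit step, and as equality-constraint rows (with the neighbouring
coupling folded onto the diagonal) in the implicit matrix.

Axial links between neighbours of unequal size use half-lengths in series:
r_link(i, pa) = (r̂_a,i Δx_i + r̂_a,pa Δx_pa)/2, which reduces to r̂_a Δx on
uniform chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import membrane
from .membrane import ElectricalParams, GatingState
from .morphology import NeuriteTree
from .recording import Recording

__all__ = [
    "SolverConfig",
    "SimulationState",
    "ImplicitSystem",
    "RectPulse",
    "PulseTrain",
    "StimulusProtocol",
    "DivergenceError",
    "LinearSolveError",
    "Assembly",
    "critical_time_step",
    "critical_time_step_per_element",
    "spectral_radius",
    "stability_threshold_bisect",
    "explicit_update_matrix",
    "explicit_step",
    "assemble_implicit",
    "apply_boundary_rows",
    "implicit_step",
    "run_simulation",
]

logger = logging.getLogger("cabletree")


class DivergenceError(RuntimeError):
    """Non-finite membrane potential encountered during time stepping."""

    def __init__(self, message, step=None, element=None, last_state=None):
        super().__init__(message)
        self.step = step
        self.element = element
        self.last_state = last_state


class LinearSolveError(RuntimeError):
    """Implicit linear system failed to reach the residual tolerance."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


# ----------------------------------------------------------------------
# Configuration, state, stimulus
# ----------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Time-integration settings.

    ``dt`` is normally derived as ``eta * Δt_c``; the explicit scheme
    requires eta ≤ 1 while the implicit scheme permits eta ≫ 1.  Setting
    ``dt`` explicitly overrides eta.
    """

    scheme: str = "explicit"
    eta: float = 0.9
    dt: float | None = None
    duration: float = 0.0
    linear_tol: float = 1e-10
    max_linear_iter: int = 200
    decimation: int | None = None   # record every k-th step; None = auto

    def __post_init__(self):
        if self.scheme not in ("explicit", "implicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.scheme == "explicit" and self.eta > 1.0:
            raise ValueError("explicit scheme requires eta <= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class SimulationState:
    """Membrane potential per element, gating state per HH element, time."""

    V: np.ndarray
    gates: GatingState
    t: float = 0.0
    step_index: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(self.V.copy(), self.gates.copy(),
                               self.t, self.step_index)


@dataclass(frozen=True)
class RectPulse:
    """Rectangular current pulse: ``amplitude`` (A) on [start, start+duration)."""

    start: float
    duration: float
    amplitude: float

    def current(self, t: float) -> float:
        return self.amplitude if self.start <= t < self.start + self.duration else 0.0


@dataclass(frozen=True)
class PulseTrain:
    """``count`` rectangular pulses of ``pulse_duration`` every ``period``."""

    start: float
    period: float
    count: int
    pulse_duration: float
    amplitude: float

    def current(self, t: float) -> float:
        if t < self.start:
            return 0.0
        k = math.floor((t - self.start) / self.period)
        if k >= self.count:
            return 0.0
        phase = (t - self.start) - k * self.period
        return self.amplitude if phase < self.pulse_duration else 0.0


class StimulusProtocol:
    """External input currents: (element index, waveform) pairs."""

    def __init__(self, items=()):
        self.items = [(int(i), w) for i, w in items]
        for _, w in self.items:
            if not np.isfinite(w.amplitude):
                raise ValueError("stimulus amplitude must be finite")

    def validate(self, n_elements: int) -> None:
        for i, _ in self.items:
            if not (0 <= i < n_elements):
                raise ValueError(f"stimulus element index {i} out of range")

    def current_vector(self, t: float, out: np.ndarray) -> np.ndarray:
        out[:] = 0.0
        for i, w in self.items:
            out[i] += w.current(t)
        return out

    def __bool__(self):
        return bool(self.items)


# ----------------------------------------------------------------------
# Electrical assembly: lumped per-element arrays
# ----------------------------------------------------------------------

def _series_shell_sums(d, h, h_my, n_my, const_mem, const_my, reciprocal):
    """Vectorized bare-shell + myelin-layer series sums.

    ``reciprocal`` True -> capacitance style ((Σ 1/c_k)⁻¹ per length),
    False -> resistance style (Σ r_k per length).
    """
    d = np.asarray(d, float)
    base = const_mem * h / (np.pi * d)           # h/(C_m π d)  or  ρ_m h/(π d)
    total = base.copy()
    mask = n_my > 0
    if np.any(mask):
        kmax = int(n_my.max())
        ks = np.arange(1, kmax + 1)
        dmy = (d[mask, None] + 2.0 * h[mask, None]
               + 2.0 * (ks[None, :] - 1) * h_my[mask, None])
        layer = const_my * h_my[mask, None] / (np.pi * dmy)
        layer = np.where(ks[None, :] <= n_my[mask, None], layer, 0.0)
        total[mask] = base[mask] + layer.sum(axis=1)
    return 1.0 / total if reciprocal else total


class Assembly:
    """Per-element lumped electrical quantities for one (tree, params) pair.

    Precomputes element capacitances, passive (W, K), axial link
    conductances to the parent, and per-element HH channel parameters
    (optionally modified by a channel-alteration ``overlay`` mapping element
    index -> alteration; see :mod:`cabletree.mechanics`).  E_L is resolved
    once from the *unaltered* parameters and frozen.
    """

    def __init__(self, tree: NeuriteTree, params: ElectricalParams,
                 overlay: dict | None = None):
        if len(tree) == 0:
            raise ValueError("empty tree")
        self.tree = tree
        a = tree.arrays()
        self.n = a.n
        self.pa = a.pa
        self.hh = np.nonzero(a.is_hh)[0]
        self.is_hh = a.is_hh
        terminals = np.nonzero(a.rc == np.arange(a.n))[0]
        self.terminals = terminals[terminals != 0]
        if self.hh.size and params.G_L <= 0:
            raise ValueError("HH elements present but G_L <= 0")
        self.params = params.with_leak_reversal() if self.hh.size else params
        p = self.params

        h_arr = a.h
        # axial: half-lengths in series between i and its parent
        r_hat_a = membrane.axial_resistance_per_length(p.rho_a, a.d)
        own = r_hat_a * a.dx
        link_r = 0.5 * (own + own[self.pa])
        with np.errstate(divide="ignore"):
            self.g_pa = 1.0 / link_r
        self.g_pa[0] = 0.0
        self.g_self = 1.0 / own          # own-element axial conductance (Δt_c)

        # element capacitance c_mm = ĉ_m Δx (myelin layers in series)
        c_hat = _series_shell_sums(a.d, h_arr, a.h_my, a.n_my,
                                   1.0 / p.C_m, 1.0 / p.C_my if p.C_my > 0 else 0.0,
                                   reciprocal=True)
        self.c_el = c_hat * a.dx

        # passive (CT) membrane coefficients, zero placeholders on HH rows
        r_hat_m = _series_shell_sums(a.d, h_arr, a.h_my, a.n_my,
                                     p.rho_m, p.rho_my, reciprocal=False)
        g_m = a.dx / r_hat_m                       # lumped 1/r_m
        self.W_base = np.where(a.is_hh, 0.0, -g_m)
        self.K_base = np.where(a.is_hh, 0.0, p.V_rest * g_m)

        # HH per-element channel parameters (lumped, S), with overlay
        hh = self.hh
        geom = np.pi * a.d[hh] * a.dx[hh] / h_arr[hh]
        self.gbar_na = geom * p.Gbar_Na
        self.gbar_k = geom * p.Gbar_K
        self.g_l = geom * p.G_L
        self.e_na = np.full(hh.size, p.E_Na)
        self.e_k = np.full(hh.size, p.E_K)
        self.e_l = p.E_L if p.E_L is not None else 0.0
        self.v_shift = np.zeros(hh.size)
        if overlay:
            pos_of = {int(e): j for j, e in enumerate(hh)}
            for idx, alt in overlay.items():
                if int(idx) not in pos_of:
                    raise ValueError(
                        f"channel alteration applied to non-HH element {idx}")
                j = pos_of[int(idx)]
                self.gbar_na[j] *= getattr(alt, "gbar_na_scale", 1.0)
                self.gbar_k[j] *= getattr(alt, "gbar_k_scale", 1.0)
                self.g_l[j] *= getattr(alt, "g_l_scale", 1.0)
                self.e_na[j] += getattr(alt, "dE_Na", 0.0)
                self.e_k[j] += getattr(alt, "dE_K", 0.0)
                self.v_shift[j] += getattr(alt, "rate_v_shift", 0.0)

    # -- membrane coefficients -----------------------------------------

    def wk(self, gates: GatingState) -> tuple[np.ndarray, np.ndarray]:
        """Lumped (W, K) arrays for all elements at the given gating state."""
        W = self.W_base.copy()
        K = self.K_base.copy()
        if self.hh.size:
            m = np.asarray(gates.m)
            hg = np.asarray(gates.h_gate)
            nn = np.asarray(gates.n)
            g_na = self.gbar_na * m**3 * hg
            g_k = self.gbar_k * nn**4
            W[self.hh] = -(g_na + g_k + self.g_l)
            K[self.hh] = g_na * self.e_na + g_k * self.e_k + self.g_l * self.e_l
        return W, K

    def rest_gates(self) -> GatingState:
        """Gating steady state at V_rest (rate shifts applied)."""
        p = self.params
        veff = p.V_rest - self.v_shift
        return membrane.gate_steady_state(veff, p.V_rest, p.alpha_h_scale)

    def rest_state(self) -> SimulationState:
        return SimulationState(V=np.full(self.n, self.params.V_rest),
                               gates=self.rest_gates(), t=0.0, step_index=0)

    def step_gates(self, gates: GatingState, V: np.ndarray, dt: float) -> GatingState:
        if not self.hh.size:
            return gates
        p = self.params
        return membrane.gate_step(gates, V[self.hh], dt, p.V_rest,
                                  p.alpha_h_scale, v_shift=self.v_shift)

    # -- axial currents -------------------------------------------------

    def axial_currents(self, V: np.ndarray) -> np.ndarray:
        """Net axial current into each element through its parent/child links."""
        e = self.g_pa * (V[self.pa] - V)          # current parent -> element
        acc = np.bincount(self.pa[1:], weights=e[1:], minlength=self.n)
        return e - acc


# ----------------------------------------------------------------------
# Stability
# ----------------------------------------------------------------------

def critical_time_step_per_element(tree: NeuriteTree,
                                   params: ElectricalParams) -> np.ndarray:
    """Per-element stability bounds 2B_i/(C_i + 4 A_i/Δx_i²), HH elements
    evaluated with rest-state conductances."""
    asm = Assembly(tree, params)
    W, _ = asm.wk(asm.rest_gates())
    return 2.0 * asm.c_el / (-W + 4.0 * asm.g_self)


def critical_time_step(tree: NeuriteTree, params: ElectricalParams) -> float:
    """Critical explicit time step Δt_c = min_i 2B_i/(C_i + 4 A_i/Δx_i²) (s).

    The Fourier constant 4 is the worst-mode (θ = π) amplification bound of
    the forward-time/centred-space scheme on a uniform unbranched chain; the
    bound is conservative on heterogeneous trees (the derivation neglects
    branching and heterogeneity) and is verified against the exact
    spectral-radius oracle in the test suite.
    """
    return float(np.min(critical_time_step_per_element(tree, params)))


def spectral_radius(update_matrix: np.ndarray) -> float:
    """Largest absolute eigenvalue of the (dense) update matrix."""
    m = np.asarray(update_matrix)
    return float(np.max(np.abs(np.linalg.eigvals(m))))


def explicit_update_matrix(tree: NeuriteTree, params: ElectricalParams,
                           dt: float) -> np.ndarray:
    """Dense linearized one-step update matrix of the explicit scheme,
    including the boundary-overwrite projection (HH elements linearized at
    rest-state conductances).  Oracle-scale only (dense N×N)."""
    asm = Assembly(tree, params)
    W, _ = asm.wk(asm.rest_gates())
    n = asm.n
    L = np.zeros((n, n))
    for i in range(1, n):
        g = asm.g_pa[i]
        p = asm.pa[i]
        L[i, i] -= g
        L[p, p] -= g
        L[i, p] += g
        L[p, i] += g
    E = np.eye(n) + dt * (np.diag(W) + L) / asm.c_el[:, None]
    P = np.eye(n)
    if n > 1:
        P[0, 0] = 0.0
        P[0, 1] = 1.0
        for t in asm.terminals:
            if n == 2 and t == 1:
                continue
            P[t, t] = 0.0
            P[t, asm.pa[t]] = 1.0
    return P @ E


def stability_threshold_bisect(tree: NeuriteTree, params: ElectricalParams,
                               rel_tol: float = 1e-4) -> float:
    """Exact explicit stability threshold: bisection on ρ(update matrix) = 1."""
    lo = critical_time_step(tree, params)
    # bracket: formula is conservative, so lo should be stable
    while spectral_radius(explicit_update_matrix(tree, params, lo)) > 1.0 + 1e-12:
        lo *= 0.5
    hi = lo * 2.0
    while spectral_radius(explicit_update_matrix(tree, params, hi)) <= 1.0 + 1e-12:
        hi *= 2.0
    while (hi - lo) > rel_tol * lo:
        mid = 0.5 * (lo + hi)
        if spectral_radius(explicit_update_matrix(tree, params, mid)) <= 1.0 + 1e-12:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# Explicit scheme
# ----------------------------------------------------------------------

def _explicit_advance(asm: Assembly, state: SimulationState, dt: float,
                      stimulus: StimulusProtocol | None,
                      i_buf: np.ndarray) -> SimulationState:
    V = state.V
    W, K = asm.wk(state.gates)
    rhs = W * V + K + asm.axial_currents(V)
    if stimulus:
        rhs += stimulus.current_vector(state.t, i_buf)
    V1 = V + (dt / asm.c_el) * rhs
    if asm.n > 1:
        V1[0] = V1[1]
        for t in asm.terminals:
            if asm.n == 2 and t == 1:
                continue
            V1[t] = V1[asm.pa[t]]
    if not np.all(np.isfinite(V1)):
        bad = int(np.nonzero(~np.isfinite(V1))[0][0])
        raise DivergenceError(
            f"non-finite potential at element {bad} after step "
            f"{state.step_index + 1} (t = {state.t + dt:.6g} s)",
            step=state.step_index + 1, element=bad, last_state=state)
    gates = asm.step_gates(state.gates, V1, dt)
    return SimulationState(V=V1, gates=gates, t=state.t + dt,
                           step_index=state.step_index + 1)


def explicit_step(state: SimulationState, tree: NeuriteTree,
                  params: ElectricalParams,
                  stimulus: StimulusProtocol | None, dt: float,
                  _assembly: Assembly | None = None) -> SimulationState:
    """One forward-Euler step; warns (does not block) above Δt_c."""
    asm = _assembly or Assembly(tree, params)
    if _assembly is None and dt > critical_time_step(tree, params):
        import warnings
        warnings.warn("explicit step with dt above the critical time step",
                      stacklevel=2)
    return _explicit_advance(asm, state, dt, stimulus, np.zeros(asm.n))


# ----------------------------------------------------------------------
# Implicit scheme
# ----------------------------------------------------------------------

@dataclass
class ImplicitSystem:
    """One backward-Euler linear system Ã Vⁿ⁺¹ = b in CSR form."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    boundary_applied: bool = False


def _implicit_entries(asm: Assembly, gates: GatingState, dt: float):
    """COO entries of the raw (pre-boundary) backward-Euler matrix."""
    n = asm.n
    W, K = asm.wk(gates)
    rows, cols, vals = [], [], []
    diag = asm.c_el / dt - W
    tree = asm.tree
    for i, el in enumerate(tree.elements):
        beta = diag[i]
        if i > 0:
            g = asm.g_pa[i]
            beta += g
            rows.append(i); cols.append(el.pa); vals.append(-g)     # alpha
        if el.rc != i:
            g = asm.g_pa[el.rc]
            beta += g
            rows.append(i); cols.append(el.rc); vals.append(-g)     # delta
        if el.lc is not None:
            g = asm.g_pa[el.lc]
            beta += g
            rows.append(i); cols.append(el.lc); vals.append(-g)     # gamma
        rows.append(i); cols.append(i); vals.append(beta)
    return rows, cols, vals


def assemble_implicit(tree: NeuriteTree, params: ElectricalParams,
                      gates: GatingState, dt: float,
                      stimulus: StimulusProtocol | None = None,
                      t: float = 0.0, V: np.ndarray | None = None,
                      _assembly: Assembly | None = None) -> ImplicitSystem:
    """Assemble the backward-Euler system for Vⁿ⁺¹ given the state at Vⁿ.

    Per element: α = −g_pa couples to the parent, δ = −g_rc to the right
    child, γ = −g_lc to the left child (branchings only), and the diagonal
    β = ĉ_m Δx/dt − W Δx + Σ link conductances; the right-hand side is
    b = ĉ_m Δx Vⁿ/dt + K Δx + i_input(tⁿ) (the Vⁿ term is included when
    ``V`` is given).  W, K are evaluated with the gates at Vⁿ
    (semi-implicit linearization).  Boundary rows are not yet applied.
    """
    asm = _assembly or Assembly(tree, params)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rows, cols, vals = _implicit_entries(asm, gates, dt)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(asm.n, asm.n))
    _, K = asm.wk(gates)
    rhs = K.copy()
    if V is not None:
        rhs += asm.c_el / dt * np.asarray(V, float)
    if stimulus:
        rhs += stimulus.current_vector(t, np.zeros(asm.n))
    return ImplicitSystem(matrix=mat, rhs=rhs)


def apply_boundary_rows(system: ImplicitSystem, tree: NeuriteTree) -> ImplicitSystem:
    """Replace boundary rows by sealed-end equality constraints.

    Element 0's row becomes V_0ⁿ⁺¹ − V_1ⁿ⁺¹ = 0 and element 1's parent
    coupling is folded into its diagonal; each terminal row becomes
    V_tⁿ⁺¹ − V_paⁿ⁺¹ = 0 with the parent's child coupling likewise folded.
    (On a 2-element chain only the root constraint is applied, keeping the
    system nonsingular.)
    """
    n = len(tree)
    if n <= 1:
        system.boundary_applied = True
        return system
    A = system.matrix.tolil()
    b = system.rhs
    # root ghost: V0 = V1
    alpha_10 = A[1, 0]
    A[1, 1] = A[1, 1] + alpha_10
    A[1, 0] = 0.0
    A.rows[0], A.data[0] = [0, 1], [1.0, -1.0]
    b[0] = 0.0
    arr = tree.arrays()
    terminals = np.nonzero(arr.rc == np.arange(n))[0]
    for t in terminals:
        t = int(t)
        if t == 0 or (n == 2 and t == 1):
            continue
        p = int(arr.pa[t])
        coupling = A[p, t]
        A[p, p] = A[p, p] + coupling
        A[p, t] = 0.0
        # constraint row: +1 at column t, -1 at column p (p < t always)
        A.rows[t] = [p, t]
        A.data[t] = [-1.0, 1.0]
        b[t] = 0.0
    system.matrix = A.tocsr()
    system.matrix.eliminate_zeros()
    system.boundary_applied = True
    return system


def implicit_step(state: SimulationState, tree: NeuriteTree,
                  params: ElectricalParams,
                  stimulus: StimulusProtocol | None, dt: float,
                  config: SolverConfig | None = None,
                  _assembly: Assembly | None = None,
                  _cache: dict | None = None) -> SimulationState:
    """One backward-Euler step: solve the quasi-tridiagonal system, then
    advance the gates at Vⁿ⁺¹."""
    asm = _assembly or Assembly(tree, params)
    tol = config.linear_tol if config else 1e-10
    system = assemble_implicit(tree, params, state.gates, dt, stimulus,
                               state.t, V=state.V, _assembly=asm)
    apply_boundary_rows(system, tree)
    A = system.matrix.tocsc()
    if _cache is not None and asm.hh.size == 0:
        lu = _cache.get("lu")
        if lu is None:
            lu = spla.splu(A)
            _cache["lu"] = lu
        V1 = lu.solve(system.rhs)
    else:
        V1 = spla.splu(A).solve(system.rhs)
    res = np.linalg.norm(A @ V1 - system.rhs)
    scale = np.linalg.norm(system.rhs)
    if scale > 0 and res / scale > tol:
        raise LinearSolveError(
            f"implicit solve residual {res / scale:.3e} above tolerance {tol:.1e}",
            residuals=[res / scale])
    if not np.all(np.isfinite(V1)):
        bad = int(np.nonzero(~np.isfinite(V1))[0][0])
        raise DivergenceError(
            f"non-finite potential at element {bad} after step "
            f"{state.step_index + 1}", step=state.step_index + 1,
            element=bad, last_state=state)
    gates = asm.step_gates(state.gates, V1, dt)
    return SimulationState(V=V1, gates=gates, t=state.t + dt,
                           step_index=state.step_index + 1)


# ----------------------------------------------------------------------
# Run loop
# ----------------------------------------------------------------------

def run_simulation(tree: NeuriteTree, params: ElectricalParams,
                   config: SolverConfig,
                   stimulus: StimulusProtocol | None = None,
                   probes: list[int] | None = None,
                   mech=None, seed: int | None = None) -> Recording:
    """Advance the chosen scheme for the configured duration and record the
    probe potentials.

    Mechanical loading (``mech``, a :class:`cabletree.mechanics
    .MechanicalLoading`) is applied once, quasi-statically, before time
    stepping: the element geometry is strained and any channel alteration
    overlay is attached.  ``dt`` defaults to ``eta * Δt_c`` computed on the
    (strained) tree.
    """
    overlay = None
    if mech is not None:
        from . import mechanics
        tree, overlay = mechanics.apply_loading(tree, mech)
    asm = Assembly(tree, params, overlay)
    if probes is None:
        probes = [asm.n - 1]
    for pidx in probes:
        if not (0 <= pidx < asm.n):
            raise ValueError(f"invalid probe element index {pidx}")
    if stimulus:
        stimulus.validate(asm.n)

    dtc = critical_time_step(tree, params)
    dt = config.dt if config.dt is not None else config.eta * dtc
    n_steps = int(math.ceil(config.duration / dt - 1e-12)) if config.duration > 0 else 0
    decim = config.decimation or max(1, math.ceil(max(1, n_steps) / 1e5))
    n_samples = n_steps // decim + 1

    arr = tree.arrays()
    positions = arr.axial_pos[probes]
    times = np.empty(n_samples)
    traces = np.empty((n_samples, len(probes)))
    state = asm.rest_state()
    times[0] = state.t
    traces[0] = state.V[probes]

    i_buf = np.zeros(asm.n)
    cache: dict = {}
    k = 1
    for step in range(1, n_steps + 1):
        if config.scheme == "explicit":
            state = _explicit_advance(asm, state, dt, stimulus, i_buf)
        else:
            state = implicit_step(state, tree, params, stimulus, dt,
                                  config, _assembly=asm, _cache=cache)
        if step % decim == 0:
            times[k] = state.t
            traces[k] = state.V[probes]
            k += 1
        if step % 10000 == 0:
            logger.info("step %d/%d t=%.6g s max|V|=%.4g V",
                        step, n_steps, state.t, float(np.max(np.abs(state.V))))
    metadata = {
        "scheme": config.scheme,
        "eta": config.eta,
        "dt": dt,
        "dtc": dtc,
        "duration": config.duration,
        "n_steps": n_steps,
        "decimation": decim,
        "n_elements": asm.n,
        "n_branching": int(np.count_nonzero(arr.fb)),
        "seed": seed,
        "V_rest": params.V_rest,
        "strain": getattr(mech, "macro_strain", None) if mech is not None else None,
    }
    return Recording(times=times[:k], V=traces[:k], probes=list(probes),
                     positions=positions, metadata=metadata)
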