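"""Analytic oracles and derived metrics.

Closed-form sealed-end cable solutions (the classic steady-state benchmark
for passive-cable solvers), conduction velocity and action-potential
amplitude metrics on recordings, and convergence-order estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import membrane, solvers
from .membrane import ElectricalParams
from .morphology import CT, ElementSpec, NeuriteTree, tree_from_specs
from .recording import Recording

__all__ = [
    "CableAnalytic",
    "MetricError",
    "sealed_cable_steady_state",
    "conduction_velocity",
    "ap_amplitude",
    "convergence_order",
    "build_uniform_cable",
    "steady_state_implicit",
    "passive_cable_profile",
    "passive_cable_benchmark",
    "spatial_convergence_order",
    "temporal_convergence_order",
]


class MetricError(RuntimeError):
    """A derived metric could not be computed from the recording."""


@dataclass(frozen=True)
class CableAnalytic:
    """Closed-form description of a uniform sealed-end passive cable with a
    constant current I injected at x = 0.

    lam = √(r̂_m/r̂_a) is the space constant, R_inf = √(r̂_m·r̂_a) the input
    resistance of the semi-infinite cable, L the cable length.
    """

    lam: float
    R_inf: float
    L: float
    I: float

    def __post_init__(self):
        if min(self.lam, self.R_inf, self.L) <= 0:
            raise ValueError("lam, R_inf and L must be positive")

    @classmethod
    def from_cable(cls, params: ElectricalParams, d: float, h: float,
                   L: float, I: float) -> "CableAnalytic":
        r_hat_m = membrane.membrane_resistance_times_length(d, h, params.rho_m)
        r_hat_a = membrane.axial_resistance_per_length(params.rho_a, d)
        return cls(lam=math.sqrt(r_hat_m / r_hat_a),
                   R_inf=math.sqrt(r_hat_m * r_hat_a), L=L, I=I)


def sealed_cable_steady_state(x, oracle: CableAnalytic):
    """Steady-state potential offset V(x) − V_rest of the sealed-end cable:

        I · R_inf · cosh((L−x)/λ) / sinh(L/λ)
    """
    x = np.asarray(x, float)
    lam, L = oracle.lam, oracle.L
    # cosh((L-x)/lam)/sinh(L/lam), written overflow-safe for long cables
    a = (L - x) / lam
    b = L / lam
    ratio = (np.exp(a - b) + np.exp(-a - b)) / (1.0 - np.exp(-2.0 * b))
    return oracle.I * oracle.R_inf * ratio


def _threshold_crossing(times: np.ndarray, trace: np.ndarray,
                        threshold: float, name: str) -> float:
    below = trace < threshold
    ups = np.nonzero(below[:-1] & ~below[1:])[0]
    if ups.size == 0:
        raise MetricError(f"trace at probe {name} never crosses threshold")
    if ups.size > 1:
        raise MetricError(f"trace at probe {name} crosses threshold "
                          f"{ups.size} times (expected exactly one)")
    i = int(ups[0])
    f = (threshold - trace[i]) / (trace[i + 1] - trace[i])
    return float(times[i] + f * (times[i + 1] - times[i]))


def conduction_velocity(rec: Recording, probe_a: int, probe_b: int,
                        threshold: float | None = None) -> float:
    """Propagation speed (m/s) between two probes from the upward
    threshold-crossing times (linear interpolation between samples).

    Default threshold: V_rest + 20 mV.
    """
    if threshold is None:
        v_rest = rec.metadata.get("V_rest")
        if v_rest is None:
            raise MetricError("no threshold given and no V_rest in metadata")
        threshold = v_rest + 0.020
    ta = _threshold_crossing(rec.times, rec.trace(probe_a), threshold, str(probe_a))
    tb = _threshold_crossing(rec.times, rec.trace(probe_b), threshold, str(probe_b))
    if tb == ta:
        raise MetricError("identical crossing times at both probes")
    return float((rec.position(probe_b) - rec.position(probe_a)) / (tb - ta))


def ap_amplitude(rec: Recording, probe: int,
                 v_rest: float | None = None) -> float:
    """Peak depolarization max(trace) − V_rest at one probe (V)."""
    if v_rest is None:
        v_rest = rec.metadata.get("V_rest")
        if v_rest is None:
            raise MetricError("no V_rest given or found in metadata")
    return float(np.max(rec.trace(probe)) - v_rest)


def convergence_order(steps, errors) -> float | None:
    """Observed order: least-squares slope of log(error) vs log(step).

    Returns None (with a warning) when the error ladder is not monotone
    decreasing or hits machine noise, in which case no order is claimed.
    """
    steps = np.asarray(steps, float)
    errors = np.asarray(errors, float)
    if len(steps) < 2:
        raise ValueError("need at least two refinement levels")
    order = np.argsort(steps)[::-1]          # coarse -> fine
    e = errors[order]
    if np.any(e <= 0) or np.any(np.diff(e) >= 0):
        warnings.warn("non-monotone (or machine-noise) error ladder; "
                      "no convergence order claimed", stacklevel=2)
        return None
    slope = np.polyfit(np.log(steps[order]), np.log(e), 1)[0]
    return float(slope)


# ----------------------------------------------------------------------
# Passive-cable benchmark (uniform cable, current step, sealed ends)
# ----------------------------------------------------------------------

def build_uniform_cable(n_physical: int, dx: float, d: float,
                        h: float = 1e-8) -> NeuriteTree:
    """Unbranched CT chain with one ghost element at each sealed end.

    Elements 1..n_physical are the physical cable of length n_physical·dx;
    elements 0 and n_physical+1 are the boundary ghosts whose potentials are
    copies of their neighbours (the sealed-end condition), so the zero-flux
    plane sits exactly at each physical end (mirror ghost).
    """
    root = ElementSpec(mm=CT, dx=dx, d=d, h=h)
    tip = root
    for _ in range(n_physical + 1):
        nxt = ElementSpec(mm=CT, dx=dx, d=d, h=h)
        tip.children.append(nxt)
        tip = nxt
    return tree_from_specs(root, {"builder": "uniform_cable",
                                  "n_physical": n_physical, "dx": dx})


def steady_state_implicit(tree: NeuriteTree, params: ElectricalParams,
                          stimulus: solvers.StimulusProtocol,
                          dt: float, tol: float = 1e-12,
                          max_steps: int = 10000) -> np.ndarray:
    """Backward-Euler relaxation to the steady state (passive trees).

    Backward Euler is unconditionally stable, so a time step much larger
    than the membrane time constant converges geometrically to the steady
    state of the discrete system.
    """
    asm = solvers.Assembly(tree, params)
    state = asm.rest_state()
    cfg = solvers.SolverConfig(scheme="implicit", eta=1.0, dt=dt, duration=0.0)
    cache: dict = {}
    for _ in range(max_steps):
        prev = state.V
        state = solvers.implicit_step(state, tree, params, stimulus, dt,
                                      cfg, _assembly=asm, _cache=cache)
        dv = np.max(np.abs(state.V - prev))
        ref = max(np.max(np.abs(state.V - params.V_rest)), 1e-300)
        if dv <= tol * ref:
            return state.V
    raise RuntimeError("steady-state relaxation did not converge")


def passive_cable_profile(dx: float, L: float, params: ElectricalParams,
                          d: float, h: float, I: float):
    """Numeric steady-state profile of the benchmark cable.

    Returns (x centres of physical elements, V − V_rest, analytic oracle).
    Current I enters the first physical element (the compartment [0, dx]).
    """
    n_phys = int(round(L / dx))
    tree = build_uniform_cable(n_phys, L / n_phys, d, h)
    dx = L / n_phys
    stim = solvers.StimulusProtocol([(1, solvers.RectPulse(0.0, np.inf, I))])
    tau = (membrane.membrane_resistance_times_length(d, h, params.rho_m)
           * membrane.capacitance_per_length(d, h, params.C_m))
    V = steady_state_implicit(tree, params, stim, dt=10.0 * float(tau))
    x = (np.arange(1, n_phys + 1) - 0.5) * dx
    oracle = CableAnalytic.from_cable(params, d, h, L, I)
    return x, V[1:n_phys + 1] - params.V_rest, oracle


def passive_cable_benchmark(dx: float, L: float, params: ElectricalParams,
                            d: float = 1e-6, h: float = 1e-8,
                            I: float = 2e-11) -> dict:
    """Steady-state L∞ error of the solver against the cosh solution.

    The error is the maximum absolute deviation over all physical elements,
    normalized by the peak analytic offset (Rallpack-style normalization).
    """
    x, v_num, oracle = passive_cable_profile(dx, L, params, d, h, I)
    v_ana = sealed_cable_steady_state(x, oracle)
    err = float(np.max(np.abs(v_num - v_ana)) / np.max(np.abs(v_ana)))
    return {"dx": dx, "lambda": oracle.lam, "n_physical": x.size,
            "linf_rel_error": err, "peak_offset_V": float(np.max(np.abs(v_ana)))}


def spatial_convergence_order(L: float, params: ElectricalParams,
                              d: float = 1e-6, h: float = 1e-8,
                              I: float = 2e-11,
                              levels=(10, 20, 40, 80)) -> tuple[float | None, list]:
    """Observed spatial order of the steady-state benchmark on a Δx ladder
    (levels = physical elements per cable)."""
    dxs, errs = [], []
    for n in levels:
        r = passive_cable_benchmark(L / n, L, params, d, h, I)
        dxs.append(r["dx"])
        errs.append(r["linf_rel_error"])
    return convergence_order(dxs, errs), list(zip(dxs, errs))


def temporal_convergence_order(tree: NeuriteTree, params: ElectricalParams,
                               stimulus: solvers.StimulusProtocol,
                               T: float, scheme: str = "explicit",
                               etas=(0.8, 0.4, 0.2, 0.1),
                               eta_ref: float = 0.025) -> tuple[float | None, list]:
    """Observed temporal order at fixed Δx: L∞ error at time T against a
    fine-Δt reference run of the same scheme."""
    dtc = solvers.critical_time_step(tree, params)

    def final_v(eta):
        dt = eta * dtc
        n = int(round(T / dt))
        cfg = solvers.SolverConfig(
            scheme=scheme, eta=min(eta, 1.0) if scheme == "explicit" else eta,
            dt=T / n, duration=T, decimation=max(1, n))
        rec = solvers.run_simulation(tree, params, cfg, stimulus,
                                     probes=list(range(len(tree))))
        return rec.V[-1]

    ref = final_v(eta_ref)
    dts, errs = [], []
    for eta in etas:
        v = final_v(eta)
        dts.append(eta * dtc)
        errs.append(float(np.max(np.abs(v - ref))))
    return convergence_order(dts, errs), list(zip(dts, errs))
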