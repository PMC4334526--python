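"""Explicit/implicit schemes: stability, assembly structure, boundaries,
rest fixed point, propagation, consistency."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from cabletree import presets, solvers
from cabletree.membrane import gate_steady_state
from cabletree.morphology import CT, HH, ElementSpec, tree_from_specs
from cabletree.solvers import (
    Assembly,
    RectPulse,
    SolverConfig,
    StimulusProtocol,
    assemble_implicit,
    apply_boundary_rows,
    critical_time_step,
    critical_time_step_per_element,
    explicit_step,
    explicit_update_matrix,
    implicit_step,
    run_simulation,
    spectral_radius,
    stability_threshold_bisect,
)

from conftest import random_mixed_chain


def chain(n, mm=CT, dx=1e-5, d=1e-6, n_my=0):
    root = ElementSpec(mm=mm, dx=dx, d=d, n_my=n_my, h_my=1e-8)
    tip = root
    for _ in range(n - 1):
        nxt = ElementSpec(mm=mm, dx=dx, d=d, n_my=n_my, h_my=1e-8)
        tip.children.append(nxt)
        tip = nxt
    return tree_from_specs(root)


def branched_tree(k=4, tail=5):
    """Chain 0..k-1 then a branching at k-1? No: branch at element k with two
    chains: right subtree of length ``tail`` first, left subtree after."""
    root = ElementSpec(mm=CT, dx=1e-5, d=1e-6)
    tip = root
    for _ in range(k):
        nxt = ElementSpec(mm=CT, dx=1e-5, d=1e-6)
        tip.children.append(nxt)
        tip = nxt
    for _ in range(2):
        sub = ElementSpec(mm=CT, dx=1e-5, d=1e-6)
        stip = sub
        for _ in range(tail - 1):
            nxt = ElementSpec(mm=CT, dx=1e-5, d=1e-6)
            stip.children.append(nxt)
            stip = nxt
        tip.children.append(sub)
    return tree_from_specs(root)


class TestCriticalTimeStep:
    def test_diffusion_free_limit_is_membrane_time_constant(self, squid):
        # with negligible axial coupling, Δt_c -> 2 r̂_m ĉ_m
        from cabletree import membrane
        p = dataclasses.replace(squid, rho_a=1e12)
        t = chain(1)
        r_hat_m = membrane.membrane_resistance_times_length(1e-6, 1e-8, p.rho_m)
        c_hat = membrane.capacitance_per_length(1e-6, 1e-8, p.C_m)
        assert critical_time_step(t, p) == pytest.approx(
            2 * r_hat_m * c_hat, rel=1e-6)

    def test_uniform_ct_chain_matches_bisection(self, squid):
        t = chain(50)
        dtc = critical_time_step(t, squid)
        exact = stability_threshold_bisect(t, squid)
        assert dtc == pytest.approx(exact, rel=0.02)

    def test_min_attained_matches_per_element_sweep(self, node_params):
        # dual route: per-element bounds via the PDE coefficients directly
        from cabletree.membrane import gate_steady_state, pde_coefficients
        t = random_mixed_chain(17)
        p = node_params.with_leak_reversal()
        ss = gate_steady_state(p.V_rest, p.V_rest)
        per = []
        for e in t:
            A, B, C, _ = pde_coefficients(e, p, ss if e.mm == HH else None)
            per.append(2 * B / (C + 4 * A / e.dx**2))
        got = critical_time_step_per_element(t, p)
        np.testing.assert_allclose(got, per, rtol=1e-10)
        assert critical_time_step(t, p) == pytest.approx(min(per), rel=1e-10)

    def test_empty_tree_rejected(self, squid):
        from cabletree.morphology import NeuriteTree
        with pytest.raises(ValueError):
            critical_time_step(NeuriteTree([]), squid)


class TestSpectralRadius:
    def test_identity(self):
        assert spectral_radius(np.eye(7)) == pytest.approx(1.0)

    def test_diagonal(self):
        assert spectral_radius(np.diag([0.5, -0.25])) == pytest.approx(0.5)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(0)
        n = 100
        m = (np.diag(rng.uniform(0.1, 0.9, n))
             + np.diag(rng.uniform(0.05, 0.1, n - 1), 1)
             + np.diag(rng.uniform(0.05, 0.1, n - 1), -1))
        v = rng.standard_normal(n)
        lam = 0.0
        for _ in range(10000):
            v = m @ v
            nrm = np.linalg.norm(v)
            lam, v = nrm, v / nrm
        assert spectral_radius(m) == pytest.approx(lam, rel=1e-8)


class TestExplicitStep:
    def test_rest_is_fixed_point(self, node_params):
        for t in (chain(10, CT, n_my=5), chain(10, HH)):
            asm = Assembly(t, node_params)
            s0 = asm.rest_state()
            s1 = explicit_step(s0, t, node_params, None,
                               0.5 * critical_time_step(t, node_params))
            assert np.max(np.abs(s1.V - s0.V)) < 1e-14

    def test_isolated_current_injection(self, squid):
        t = chain(2)
        asm = Assembly(t, squid)
        s0 = asm.rest_state()
        I = 1e-11
        dt = 0.5 * critical_time_step(t, squid)
        stim = StimulusProtocol([(1, RectPulse(0.0, 1.0, I))])
        s1 = explicit_step(s0, t, squid, stim, dt)
        # all coupling terms vanish at rest: ΔV_1 = dt I / (ĉ_m Δx) exactly
        assert s1.V[1] - s0.V[1] == pytest.approx(dt * I / asm.c_el[1], rel=1e-14)
        assert s1.V[0] == s1.V[1]  # sealed-end copy

    def test_three_element_hand_computation(self, squid):
        t = chain(3)
        asm = Assembly(t, squid)
        V = np.array([-0.060, -0.050, -0.070])
        from cabletree.solvers import SimulationState
        from cabletree.membrane import GatingState
        s0 = SimulationState(V=V.copy(), gates=GatingState(
            np.empty(0), np.empty(0), np.empty(0)))
        dt = 0.5 * critical_time_step(t, squid)
        s1 = explicit_step(s0, t, squid, None, dt)
        # hand evaluation, element by element, scalar arithmetic
        W, K = asm.wk(s0.gates)
        expect = np.empty(3)
        for i in range(3):
            axial = 0.0
            if i > 0:
                axial += asm.g_pa[i] * (V[i - 1] - V[i])
            if i < 2:
                axial += asm.g_pa[i + 1] * (V[i + 1] - V[i])
            expect[i] = V[i] + dt / asm.c_el[i] * (W[i] * V[i] + K[i] + axial)
        expect[0] = expect[1]
        expect[2] = expect[1]  # terminal copies its parent
        np.testing.assert_allclose(s1.V, expect, rtol=1e-14)

    def test_divergence_reported_with_context(self, squid):
        t = chain(5)
        asm = Assembly(t, squid)
        s0 = asm.rest_state()
        s0.V[2] = np.inf
        with pytest.raises(solvers.DivergenceError, match="element"):
            explicit_step(s0, t, squid, None,
                          0.5 * critical_time_step(t, squid))

    def test_warns_above_critical_step(self, squid):
        t = chain(5)
        s0 = Assembly(t, squid).rest_state()
        with pytest.warns(UserWarning, match="critical"):
            explicit_step(s0, t, squid, None,
                          2.0 * critical_time_step(t, squid))


class TestImplicitAssembly:
    def test_unbranched_chain_strictly_tridiagonal(self, squid):
        t = chain(5)
        asm = Assembly(t, squid)
        sys_ = assemble_implicit(t, squid, asm.rest_state().gates, 1e-6)
        A = sys_.matrix.toarray()
        for i in range(5):
            for j in range(5):
                if abs(i - j) > 1:
                    assert A[i, j] == 0.0

    def test_interior_row_sum_identity(self, node_params):
        t = random_mixed_chain(3)
        asm = Assembly(t, node_params)
        gates = asm.rest_gates()
        dt = 1e-7
        sys_ = assemble_implicit(t, node_params, gates, dt, _assembly=asm)
        A = sys_.matrix
        W, _ = asm.wk(gates)
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        expect = asm.c_el / dt - W
        interior = slice(1, len(t) - 1)
        np.testing.assert_allclose(rowsum[interior], expect[interior],
                                   rtol=1e-12)

    def test_branching_off_tridiagonal_pattern(self, squid):
        t = branched_tree(k=4, tail=5)
        b = next(e.index for e in t if e.fb)
        l = t[b].lc
        asm = Assembly(t, squid)
        sys_ = assemble_implicit(t, squid, asm.rest_state().gates, 1e-6,
                                 _assembly=asm)
        A = sys_.matrix.toarray()
        off = [(i, j) for i in range(len(t)) for j in range(len(t))
               if abs(i - j) > 1 and A[i, j] != 0.0]
        # exactly one (k,l)/(l,k) pair per branching
        assert off == [(b, l), (l, b)]
        assert A[b, l] == pytest.approx(-asm.g_pa[l])      # gamma
        assert A[l, b] == pytest.approx(-asm.g_pa[l])      # alpha of row l

    def test_boundary_rows_give_equal_potentials(self, squid):
        t = chain(2)
        asm = Assembly(t, squid)
        state = asm.rest_state()
        state.V[:] = [-0.060, -0.050]
        for _ in range(5):
            state = implicit_step(state, t, squid, None, 1e-6)
            assert state.V[0] == pytest.approx(state.V[1], rel=1e-14)

    def test_zero_flux_uniform_potential_preserved(self, squid):
        # sealed ends leak no axial current: with an (almost) infinite
        # membrane resistance a uniform off-rest potential must persist
        p = dataclasses.replace(squid, rho_m=1e30)
        t = chain(12)
        asm = Assembly(t, p)
        state = asm.rest_state()
        state.V[:] = -0.020
        for _ in range(1000):
            state = implicit_step(state, t, p, None, 1e-5, _assembly=asm)
        assert np.max(np.abs(state.V + 0.020)) < 1e-10

    @pytest.mark.parametrize("seed", range(100))
    def test_boundary_folded_matrix_nonsingular(self, seed, squid):
        from conftest import random_tree
        t = random_tree(seed, n_elements=25)
        asm = Assembly(t, squid)
        sys_ = assemble_implicit(t, squid, asm.rest_state().gates, 1e-6,
                                 _assembly=asm)
        apply_boundary_rows(sys_, t)
        cond = np.linalg.cond(sys_.matrix.toarray())
        assert np.isfinite(cond)
        assert cond < 1e14


class TestImplicitStep:
    def test_rest_preserved_at_large_eta(self, node_params):
        t = random_mixed_chain(21)
        dtc = critical_time_step(t, node_params)
        asm = Assembly(t, node_params)
        state = asm.rest_state()
        for _ in range(50):
            state = implicit_step(state, t, node_params, None, 100 * dtc,
                                  _assembly=asm)
        assert np.max(np.abs(state.V - node_params.V_rest)) < 1e-12

    def test_matches_dense_direct_solve(self, squid):
        t = chain(20)
        asm = Assembly(t, squid)
        state = asm.rest_state()
        state.V += np.linspace(0, 0.01, 20)
        dt = 1e-6
        stim = StimulusProtocol([(3, RectPulse(0.0, 1.0, 1e-11))])
        nxt = implicit_step(state, t, squid, stim, dt, _assembly=asm)
        sys_ = assemble_implicit(t, squid, state.gates, dt, stim, 0.0,
                                 V=state.V, _assembly=asm)
        apply_boundary_rows(sys_, t)
        dense = np.linalg.solve(sys_.matrix.toarray(), sys_.rhs)
        np.testing.assert_allclose(nxt.V, dense, atol=1e-10)


class TestRunSimulation:
    def test_zero_duration_returns_initial_state_only(self, squid):
        t = chain(8)
        rec = run_simulation(t, squid, SolverConfig(duration=0.0), probes=[3])
        assert rec.n_samples == 1
        assert rec.V[0, 0] == pytest.approx(squid.V_rest)

    def test_invalid_probe_rejected(self, squid):
        with pytest.raises(ValueError, match="probe"):
            run_simulation(chain(4), squid, SolverConfig(duration=0.0),
                           probes=[99])

    def test_deterministic_reruns_bit_identical(self, node_params):
        t = presets.myelinated_axon_fixture(n_nodes=4)[0]
        stim = StimulusProtocol([(1, RectPulse(0, 1e-4, 3e-10))])
        cfg = SolverConfig(scheme="explicit", eta=0.8, duration=2e-4)
        r1 = run_simulation(t, node_params, cfg, stim, probes=[1, 40])
        r2 = run_simulation(t, node_params, cfg, stim, probes=[1, 40])
        assert np.array_equal(r1.V, r2.V)
        assert np.array_equal(r1.times, r2.times)

    def test_hh_cable_ap_propagates(self, squid):
        # unmyelinated active cable: suprathreshold pulse fires an AP that
        # arrives later at farther probes with > 50 mV depolarization
        t = chain(150, HH, dx=1e-5)   # 1.5 mm
        stim = StimulusProtocol([(1, RectPulse(0.0, 3e-4, 1e-9))])
        cfg = SolverConfig(scheme="explicit", eta=0.9, duration=6e-3)
        probes = [40, 100]
        rec = run_simulation(t, squid, cfg, stim, probes)
        assert all(rec.trace(p).max() > squid.V_rest + 0.05 for p in probes)
        thr = squid.V_rest + 0.02
        onsets = [rec.times[np.argmax(rec.trace(p) > thr)] for p in probes]
        assert onsets[1] > onsets[0] > 0


class TestSchemeProperties:
    def test_superposition_on_passive_tree(self, squid):
        t = branched_tree(k=3, tail=8)
        cfg = SolverConfig(scheme="explicit", eta=0.9, duration=5e-5,
                           decimation=10)
        sA = StimulusProtocol([(2, RectPulse(0.0, 3e-5, 1e-11))])
        sB = StimulusProtocol([(7, RectPulse(1e-5, 2e-5, -2e-11))])
        sAB = StimulusProtocol(sA.items + sB.items)
        probes = list(range(len(t)))
        rA = run_simulation(t, squid, cfg, sA, probes)
        rB = run_simulation(t, squid, cfg, sB, probes)
        rAB = run_simulation(t, squid, cfg, sAB, probes)
        lhs = rAB.V - squid.V_rest
        rhs = (rA.V - squid.V_rest) + (rB.V - squid.V_rest)
        scale = np.max(np.abs(lhs))
        assert np.max(np.abs(lhs - rhs)) < 1e-8 * scale

    def test_schemes_converge_to_each_other(self, squid):
        # passive step response: L∞ gap shrinks monotonically as dt halves
        t = chain(40, CT, dx=2e-5)
        dtc = critical_time_step(t, squid)
        stim = StimulusProtocol([(1, RectPulse(0.0, 1.0, 1e-11))])
        T = 400 * dtc
        gaps = []
        for eta in (0.8, 0.4, 0.2, 0.1):
            dt = eta * dtc
            n = int(round(T / dt))
            cfg_e = SolverConfig(scheme="explicit", eta=eta, dt=T / n,
                                 duration=T, decimation=n)
            cfg_i = SolverConfig(scheme="implicit", eta=1.0, dt=T / n,
                                 duration=T, decimation=n)
            probes = list(range(len(t)))
            ve = run_simulation(t, squid, cfg_e, stim, probes).V[-1]
            vi = run_simulation(t, squid, cfg_i, stim, probes).V[-1]
            gaps.append(np.max(np.abs(ve - vi)))
        assert all(b < a for a, b in zip(gaps, gaps[1:]))

    def test_stability_brackets_small_sweep(self, node_params):
        # spot-check (full 50-chain sweep lives in the acceptance suite)
        for seed in (2, 9):
            t = random_mixed_chain(seed)
            dtc = critical_time_step(t, node_params)
            assert spectral_radius(
                explicit_update_matrix(t, node_params, 0.9 * dtc)) < 1.0
            assert spectral_radius(
                explicit_update_matrix(t, node_params, 1.5 * dtc)) > 1.0
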