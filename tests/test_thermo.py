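"""Macrostate sampling, free-energy landscape, heat capacity, fitting, basin."""

import dataclasses
import math

import numpy as np
import pytest

from qsfr import (
    ConstraintInventory,
    DCMParameters,
    build_framework,
    entropy_counts,
    fit_parameters,
    free_energy_landscape,
    heat_capacity_curve,
    mixing_entropy,
    native_basin,
    run_pebble_game,
    sample_grid,
    sample_macrostate,
)
from qsfr.thermo import GridSamples, HeatCapacityCurve, MacrostateSample


def test_mixing_entropy_examples():
    assert mixing_entropy(0, 0, 8, 23) == pytest.approx(0.0, abs=1e-12)
    assert mixing_entropy(8, 23, 8, 23) == pytest.approx(0.0, abs=1e-12)
    assert mixing_entropy(2, 0, 4, 0) == pytest.approx(math.log(6), rel=1e-12)
    with pytest.raises(ValueError):
        mixing_entropy(5, 0, 4, 0)


def test_degenerate_macrostates_have_zero_variance(chain_inventory):
    inv = chain_inventory
    p = DCMParameters()
    s0 = sample_macrostate(inv, 0, 0, params=p, n_samples=200, seed=1)
    assert s0.n_samples == 1  # single possible subset
    assert s0.sd_sconf_R == 0.0
    # free chain, no H-bonds: every disordered torsion bar is independent
    assert s0.s_conf_R(p) == pytest.approx(inv.m_sites * p.delta_dis)
    s_full = sample_macrostate(inv, inv.m_hb, inv.m_sites, params=p, n_samples=200, seed=1)
    assert s_full.n_samples == 1


def test_mean_energy_matches_uniform_sampling(helix_inventory):
    inv = helix_inventory
    n_hb = inv.m_hb // 2
    s = sample_macrostate(inv, n_hb, 10, n_samples=200, seed=4, collect_mech=False)
    expected = n_hb / inv.m_hb * inv.hb_energy.sum()
    sem = s.sd_u / math.sqrt(s.n_samples)
    assert abs(s.mean_u - expected) < 3 * max(sem, 1e-9)


def test_eq2_assembly_matches_pebble_counts(helix_inventory):
    """The sampler's entropy bookkeeping equals a direct pebble-game recount."""
    inv = helix_inventory
    p = DCMParameters()
    s = sample_macrostate(inv, inv.m_hb, inv.m_sites, params=p, n_samples=1, seed=9)
    fw = build_framework(
        inv.bonds, inv.sites, inv.hbonds, range(inv.m_sites), inv.n_atoms, params=p
    )
    state, _ = run_pebble_game(fw)
    counts = entropy_counts(fw, state)
    assert s.s_conf_R(p) == pytest.approx(counts.s_conf_R(p.delta_nat, p.delta_dis))
    assert s.mean_qnat == counts.q_nat
    assert s.mean_qdis == counts.q_dis


def test_landscape_weights_and_zero_temperature(helix_grid):
    p = DCMParameters()
    for t in (0.0, 200.0, 328.0, 450.0):
        L = free_energy_landscape(helix_grid, p, t)
        assert L.weights.sum() == pytest.approx(1.0)
    L0 = free_energy_landscape(helix_grid, p, 0.0)
    NH = helix_grid.hb_axis[:, None]
    NN = helix_grid.nat_axis[None, :]
    expected = helix_grid.grid_of("mean_u") - p.u_sol * NH + p.v_nat * NN
    np.testing.assert_allclose(L0.G, expected)


def test_deeper_native_entropy_favours_native_rich_nodes(helix_grid):
    p1 = DCMParameters()
    p2 = dataclasses.replace(p1, delta_nat=p1.delta_nat + 0.8)
    t = 320.0
    s1 = helix_grid.sconf_R_grid(p1)
    s2 = helix_grid.sconf_R_grid(p2)
    # raising delta_nat can only increase the entropy of every node, and the
    # gain grows with the number of independent native torsions
    gain = s2 - s1
    assert np.all(gain >= -1e-9)
    qnat = helix_grid.grid_of("mean_qnat")
    order = np.argsort(qnat.ravel())
    assert gain.ravel()[order[-1]] >= gain.ravel()[order[0]]


def _fake_grid(mean_u, sconf, m_hb, m_nat):
    """Hand-built GridSamples over a (m_hb+1) x (m_nat+1) grid."""
    class _Inv:
        pass

    inv = _Inv()
    inv.m_hb, inv.m_sites = m_hb, m_nat
    samples = {}
    for i in range(m_hb + 1):
        for j in range(m_nat + 1):
            samples[(i, j)] = MacrostateSample(
                n_hb=i, n_nat=j, n_samples=1, seed=0,
                mean_u=mean_u(i, j), sd_u=0.0,
                mean_sum_qgamma=sconf(i, j), mean_qnat=0.0, mean_qdis=0.0,
                sd_sconf_R=0.0,
            )
    return GridSamples(
        inventory=inv, hb_axis=np.arange(m_hb + 1), nat_axis=np.arange(m_nat + 1),
        samples=samples, n_samples=1, seed=0, sampling_params=DCMParameters(),
    )


def test_two_state_peak_at_crossing_temperature():
    """Ideal two-state system: C_p peaks where the two free energies cross."""
    p = DCMParameters(u_sol=0.0, v_nat=0.0)
    dH, dS = -20.0, -20.0 / 350.0 / p.R  # G crossing at T* = 350 K
    grid = _fake_grid(
        mean_u=lambda i, j: dH if i == 1 else 0.0,
        sconf=lambda i, j: dS if i == 1 else 0.0,
        m_hb=1, m_nat=0,
    )
    curve = heat_capacity_curve(grid, p, t_range=(250.0, 450.0), dt=0.5)
    assert curve.t_m == pytest.approx(350.0, abs=2.0)


def test_flat_landscape_has_zero_heat_capacity():
    p = DCMParameters(u_sol=0.0, v_nat=0.0)
    grid = _fake_grid(lambda i, j: 0.0, lambda i, j: 0.0, m_hb=3, m_nat=4)
    curve = heat_capacity_curve(grid, p, t_range=(250.0, 450.0))
    np.testing.assert_allclose(curve.cp, 0.0, atol=1e-12)


def test_tm_monotone_in_solvent_energy(helix_grid):
    tms = []
    for u in (-0.4, -0.7, -1.0, -1.3, -1.6):
        p = DCMParameters(u_sol=u)
        tms.append(heat_capacity_curve(helix_grid, p, t_range=(200.0, 500.0)).t_m)
    # a more favourable broken (solvated) state melts the network earlier
    assert all(a > b for a, b in zip(tms, tms[1:]))


def test_sampling_error_scales_as_inverse_sqrt(helix_inventory):
    inv = helix_inventory
    p = DCMParameters()

    def spread(n):
        means = [
            sample_macrostate(inv, 4, 12, params=p, n_samples=n, seed=100 + k,
                              collect_mech=False).s_conf_R(p)
            for k in range(10)
        ]
        return np.std(means)

    s25, s100 = spread(25), spread(100)
    assert s100 < s25  # tighter with more samples
    assert s25 / s100 == pytest.approx(2.0, rel=0.6)  # ~ n^(-1/2)


def test_fit_self_consistency(helix_grid):
    truth = DCMParameters()
    target = heat_capacity_curve(helix_grid, truth, t_range=(250.0, 450.0))
    init = dataclasses.replace(truth, u_sol=-1.6, v_nat=-0.7, delta_nat=2.9)
    res = fit_parameters(helix_grid, target, initial=init, t_range=(250.0, 450.0))
    assert abs(res.params.u_sol - truth.u_sol) / abs(truth.u_sol) < 0.10
    assert abs(res.params.v_nat - truth.v_nat) / abs(truth.v_nat) < 0.10
    assert abs(res.params.delta_nat - truth.delta_nat) / truth.delta_nat < 0.10
    assert abs(res.t_m - target.t_m) <= 2.0


def test_fit_from_truth_converges_immediately(helix_grid):
    truth = DCMParameters()
    target = heat_capacity_curve(helix_grid, truth, t_range=(250.0, 450.0))
    res = fit_parameters(helix_grid, target, initial=truth, t_range=(250.0, 450.0))
    assert res.residual < 1e-6
    assert abs(res.t_m - target.t_m) <= 1.0


def test_fit_tracks_shifted_melting_temperature(helix_grid):
    truth = DCMParameters()
    base_tm = heat_capacity_curve(helix_grid, truth, t_range=(250.0, 450.0)).t_m
    res = fit_parameters(helix_grid, base_tm + 10.0, initial=truth, t_range=(250.0, 450.0))
    assert abs(res.t_m - (base_tm + 10.0)) <= 2.0


def test_native_basin_two_well_oracle():
    """Hand-built two-well landscape: basin equals brute-force flood fill."""
    p = DCMParameters(u_sol=0.0, v_nat=0.0)
    # wells at (0,1) and (3,4) with a ridge between columns 2 and 3
    def energy(i, j):
        return min((i - 0) ** 2 + (j - 1) ** 2, (i - 3) ** 2 + (j - 4) ** 2) + (
            3.0 if i == 2 else 0.0
        )

    grid = _fake_grid(energy, lambda i, j: 0.0, m_hb=3, m_nat=5)
    L = free_energy_landscape(grid, p, 300.0)
    basin = native_basin(L)
    assert not basin.whole_grid
    assert basin.weights.sum() == pytest.approx(1.0)
    # oracle: flood fill from the high-N_nat minimum strictly below the saddle
    G = L.G
    saddle = basin.g_saddle
    seen = {(3, 4)}
    stack = [(3, 4)]
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if (0 <= nb[0] < G.shape[0] and 0 <= nb[1] < G.shape[1]
                    and nb not in seen and G[nb] < saddle):
                seen.add(nb)
                stack.append(nb)
    assert set(basin.nodes) == seen
    assert (3, 4) in basin.nodes and (0, 1) not in basin.nodes


def test_native_basin_single_minimum_flag():
    p = DCMParameters(u_sol=0.0, v_nat=0.0)
    grid = _fake_grid(lambda i, j: (i - 1) ** 2 + (j - 1) ** 2, lambda i, j: 0.0, 2, 2)
    basin = native_basin(free_energy_landscape(grid, p, 300.0))
    assert basin.whole_grid
    assert len(basin.nodes) == 9
    assert basin.weights.sum() == pytest.approx(1.0)


def test_macrostate_bounds_checked(helix_inventory):
    with pytest.raises(ValueError):
        sample_macrostate(helix_inventory, helix_inventory.m_hb + 1, 0)
    with pytest.raises(ValueError):
        sample_macrostate(helix_inventory, 0, helix_inventory.m_sites + 1)
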