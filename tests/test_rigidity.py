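"""Pebble game, oracle equivalence, region decomposition, entropy counts."""

import numpy as np
import pytest

from qsfr import (
    BodyBarFramework,
    CovalentBond,
    HydrogenBond,
    TorsionSite,
    build_framework,
    decompose_regions,
    entropy_counts,
    oracle_rank,
    random_bodybar_graph,
    run_pebble_game,
)


def test_empty_and_saturated_pairs():
    fw = BodyBarFramework.from_edges(1, [])
    state, indep = run_pebble_game(fw)
    assert indep.size == 0 and state.free.tolist() == [6]
    assert oracle_rank(fw) == 0

    fw = BodyBarFramework.from_edges(2, [(0, 1, 7)])
    state, indep = run_pebble_game(fw)
    assert indep.sum() == 6 and not indep[-1]  # the 7th parallel bar is redundant
    assert oracle_rank(fw, 1) == 6


def test_tree_of_six_bar_edges_is_full_rank():
    fw = random_bodybar_graph(7, n_extra_edges=0, multiplicity_range=(6, 6), seed=0)
    _, indep = run_pebble_game(fw)
    assert indep.sum() == 6 * (7 - 1)


def test_triangle_of_five_bar_edges_matches_oracle():
    fw = BodyBarFramework.from_edges(3, [(0, 1, 5), (1, 2, 5), (0, 2, 5)])
    _, indep = run_pebble_game(fw)
    assert int(indep.sum()) == oracle_rank(fw, seed=3)


def test_oracle_equivalence_random_sweep():
    for s in range(60):
        fw = random_bodybar_graph(2 + s % 11, n_extra_edges=s % 13, seed=s)
        _, indep = run_pebble_game(fw)
        assert int(indep.sum()) == oracle_rank(fw, seed=s), f"graph seed {s}"


def test_rank_is_insertion_order_invariant():
    rng = np.random.default_rng(7)
    fw = random_bodybar_graph(9, n_extra_edges=10, seed=7, random_entropies=True)
    _, ref = run_pebble_game(fw)
    for _ in range(20):
        order = rng.permutation(fw.n_bars)
        _, indep = run_pebble_game(fw, order=order)
        assert indep.sum() == ref.sum()


def test_pebble_conservation():
    fw = random_bodybar_graph(8, n_extra_edges=9, seed=3)
    state, indep = run_pebble_game(fw)
    assert indep.sum() + (~indep).sum() == fw.n_bars
    assert state.free.sum() == 6 * fw.n_vertices - indep.sum()
    assert state.free.sum() >= 6  # the six trivial rigid-body motions survive


def test_invalid_order_rejected():
    fw = random_bodybar_graph(4, n_extra_edges=2, seed=1)
    with pytest.raises(ValueError):
        run_pebble_game(fw, order=np.zeros(fw.n_bars, np.int64))


# --------------------------------------------------------------------------
# decomposition
# --------------------------------------------------------------------------


def _ring_framework(n: int, crosslink: bool = False):
    """Ring of n bodies joined by rotatable bonds, one torsion site per bond.

    Counting structural bars only: 5n bars vs 6n − 6 internal DOF, so the
    ring is flexible for n > 6, isostatically rigid at n = 6 and stressed
    below; ``crosslink`` adds a 5-bar H-bond across the ring.
    """
    bonds = [CovalentBond(i, (i + 1) % n, rotatable=True) for i in range(n)]
    sites = [
        TorsionSite(central=(i, (i + 1) % n),
                    dihedral=((i - 1) % n, i, (i + 1) % n, (i + 2) % n),
                    backbone_kind="other", residue_index=i + 1)
        for i in range(n)
    ]
    hbs = [HydrogenBond(0, 0, n // 2, energy=-4.0, gamma=1.0)] if crosslink else []
    return build_framework(bonds, sites, hbs, [], n)


def test_isostatic_ring_scores_zero():
    # hexagonal ring: 30 structural bars = 30 internal DOF, rigid with B = 0
    fw = _ring_framework(6)
    state, _ = run_pebble_game(fw)
    report = decompose_regions(fw, state)
    assert report.site_locked.all()
    assert len(set(report.rigid_cluster)) == 1
    assert report.over_B == {}
    np.testing.assert_allclose(report.site_f, 0.0)


def test_crosslinked_ring_is_stressed():
    fw = _ring_framework(6, crosslink=True)
    state, _ = run_pebble_game(fw)
    report = decompose_regions(fw, state)
    assert report.site_locked.all()
    assert sum(report.over_B.values()) == 5  # the whole H-bond is redundant
    assert np.all(report.site_f < 0)
    # all locked bonds share one over-constrained region: l = B/L = 5/6
    np.testing.assert_allclose(report.site_f, -5.0 / 6.0)


def test_underconstrained_ring_shares_collective_dof():
    # 8-ring: 40 structural bars, 42 internal DOF -> 2 collective hinge DOF
    fw = _ring_framework(8)
    state, _ = run_pebble_game(fw)
    report = decompose_regions(fw, state)
    assert not report.site_locked.any()
    regions = set(report.site_flex_region.tolist())
    assert len(regions) == 1
    r = regions.pop()
    assert report.flex_H[r] == 8
    assert report.flex_A[r] == 2  # A < H: coupled hinges
    np.testing.assert_allclose(report.site_f, 2.0 / 8.0)


def test_free_chain_single_flexible_region(chain_inventory):
    inv = chain_inventory
    fw = build_framework(inv.bonds, inv.sites, [], [], inv.n_atoms)
    state, indep = run_pebble_game(fw)
    report = decompose_regions(fw, state)
    assert not report.site_locked.any()
    regions = set(report.site_flex_region.tolist())
    assert len(regions) == 1  # one floppy region spans the whole backbone
    n_sites = len(inv.sites)
    region = regions.pop()
    assert report.flex_H[region] == n_sites
    # every torsion bar independent -> A = H and f = 1 everywhere
    assert report.flex_A[region] == n_sites
    np.testing.assert_allclose(report.site_f, 1.0)


def test_helix_interior_locked_with_redundancy(helix_inventory):
    inv = helix_inventory
    native = list(range(len(inv.sites)))
    fw = build_framework(inv.bonds, inv.sites, inv.hbonds, native, inv.n_atoms)
    state, indep = run_pebble_game(fw)
    report = decompose_regions(fw, state)
    locked = report.site_locked
    assert locked.sum() >= len(inv.sites) // 2  # interior phi/psi lock up
    assert not locked.all()                     # termini stay flexible
    assert sum(report.over_L.values()) > 0 and sum(report.over_B.values()) > 0
    # redundancy count agrees with the rank oracle
    assert int(indep.sum()) == oracle_rank(fw, seed=11)


# --------------------------------------------------------------------------
# entropy counts
# --------------------------------------------------------------------------


def test_bridging_hbond_is_fully_independent():
    bonds = [CovalentBond(0, 1, rotatable=False), CovalentBond(2, 3, rotatable=False)]
    hb = HydrogenBond(1, 1, 2, energy=-3.0, gamma=0.5)
    fw = build_framework(bonds, [], [hb], [], 4)
    state, _ = run_pebble_game(fw)
    counts = entropy_counts(fw, state)
    assert counts.q.tolist() == [5]
    assert counts.sum_q_gamma == pytest.approx(2.5)


def test_duplicated_hbond_partially_redundant():
    bonds = [CovalentBond(0, 1, rotatable=False), CovalentBond(2, 3, rotatable=False)]
    hb = HydrogenBond(1, 1, 2, energy=-3.0, gamma=0.5)
    fw = build_framework(bonds, [], [hb, hb], [], 4)
    state, _ = run_pebble_game(fw)
    counts = entropy_counts(fw, state)
    assert counts.q[0] == 5
    assert counts.q[1] < 5  # second copy cannot be fully independent


def test_entropy_counts_require_preferential_order():
    fw = _ring_framework(6, crosslink=True)
    order = np.arange(fw.n_bars)[::-1]
    state, _ = run_pebble_game(fw, order=order)
    with pytest.raises(ValueError):
        entropy_counts(fw, state)


def test_preferential_order_minimises_entropy_estimate():
    rng = np.random.default_rng(5)
    fw = random_bodybar_graph(8, n_extra_edges=14, seed=5, random_entropies=True)
    _, pref = run_pebble_game(fw)
    s_pref = float(fw.entropies[pref].sum())
    for _ in range(30):
        order = rng.permutation(fw.n_bars)
        _, indep = run_pebble_game(fw, order=order)
        assert s_pref <= float(fw.entropies[indep].sum()) + 1e-12
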