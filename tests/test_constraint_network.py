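"""Constraint inventory: covalent chemistry, H-bond detection, torsion sites,
framework assembly and ensemble propensities."""

from collections import Counter

import numpy as np
import pytest

from qsfr import (
    AtomRecord,
    Conformation,
    ConformationEnsemble,
    HBondCriteria,
    HBondEdit,
    SyntheticSystemSpec,
    assign_component_entropies,
    build_framework,
    build_peptide,
    detect_covalent_topology,
    detect_hbonds,
    enumerate_torsion_sites,
    hbond_propensity,
    perturb_ensemble,
)
from qsfr.constraint_network import UnknownResidueError


def _peptide(seq, template="coil"):
    return build_peptide(SyntheticSystemSpec(sequence=seq, fold_template=template, n_frames=2))


def test_peptide_bond_is_six_bars():
    pep = _peptide("AAAAA")
    bonds = detect_covalent_topology(pep)
    atoms = pep.atoms
    peptide = [
        b for b in bonds
        if {atoms[b.i].name, atoms[b.j].name} == {"C", "N"}
        and atoms[b.i].residue_index != atoms[b.j].residue_index
    ]
    assert len(peptide) == 4
    assert all(not b.rotatable and b.bar_count == 6 for b in peptide)


def test_glycine_phi_psi_rotatable_and_site_counts():
    pep = _peptide("GGGGG")
    bonds = detect_covalent_topology(pep)
    sites = enumerate_torsion_sites(bonds, pep)
    kinds = Counter(s.backbone_kind for s in sites)
    # N-terminal phi has no heavy neighbour on the amino side
    assert kinds == {"phi": 4, "psi": 5}


def test_proline_has_no_phi():
    pep = _peptide("AAPAA")
    bonds = detect_covalent_topology(pep)
    atoms = pep.atoms
    ring_names = {frozenset(p) for p in
                  [("N", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")]}
    ring = [
        b for b in bonds
        if atoms[b.i].residue_index == 3 and atoms[b.j].residue_index == 3
        and frozenset((atoms[b.i].name, atoms[b.j].name)) in ring_names
    ]
    assert len(ring) == 5
    assert all(not b.rotatable for b in ring)  # five-membered ring
    sites = enumerate_torsion_sites(bonds, pep)
    pro = [s.backbone_kind for s in sites if s.residue_index == 3]
    assert pro == ["psi"]


def test_unknown_residue_raises():
    pep = _peptide("AAAAA")
    import dataclasses

    atoms = [dataclasses.replace(a, residue_name="XXX") if a.residue_index == 2 else a
             for a in pep.atoms]
    with pytest.raises(UnknownResidueError, match="XXX"):
        detect_covalent_topology(Conformation(atoms))


def test_helix_backbone_hbonds(helix):
    hbs = detect_hbonds(helix)
    assert len(hbs) == 8  # i -> i+4 for every interior donor of the 12-mer
    atoms = helix.atoms
    for hb in hbs:
        assert atoms[hb.donor].name == "N"
        assert atoms[hb.acceptor].name == "O"
        assert atoms[hb.donor].residue_index - atoms[hb.acceptor].residue_index == 4
        assert hb.energy < -0.1


def test_coil_has_no_backbone_hbonds(chain):
    assert detect_hbonds(chain) == []


def test_distant_pair_not_detected():
    # two "residues" far apart: donor-acceptor at 6 A is beyond every gate
    atoms = [
        AtomRecord(1, "N", "N", 1, "ALA", "A", (0.0, 0.0, 0.0)),
        AtomRecord(2, "H", "H", 1, "ALA", "A", (1.0, 0.0, 0.0)),
        AtomRecord(3, "CA", "C", 1, "ALA", "A", (-0.8, 1.2, 0.0)),
        AtomRecord(4, "O", "O", 2, "ALA", "A", (6.0, 0.0, 0.0)),
        AtomRecord(5, "C", "C", 2, "ALA", "A", (6.8, 1.0, 0.0)),
    ]
    assert detect_hbonds(Conformation(atoms)) == []


def test_salt_bridge_flagged():
    # Arg guanidinium NH1 donating to Asp carboxylate OD1 at ideal geometry
    atoms = [
        AtomRecord(1, "NH1", "N", 1, "ARG", "A", (0.0, 0.0, 0.0)),
        AtomRecord(2, "HH11", "H", 1, "ARG", "A", (1.0, 0.0, 0.0)),
        AtomRecord(3, "CZ", "C", 1, "ARG", "A", (-0.7, 1.1, 0.0)),
        AtomRecord(4, "OD1", "O", 2, "ASP", "A", (2.9, 0.0, 0.0)),
        AtomRecord(5, "CG", "C", 2, "ASP", "A", (3.6, 1.1, 0.0)),
    ]
    hbs = detect_hbonds(Conformation(atoms))
    assert len(hbs) == 1
    assert hbs[0].is_salt_bridge


def test_no_donor_hydrogens_warns():
    atoms = [
        AtomRecord(1, "N", "N", 1, "ALA", "A", (0.0, 0.0, 0.0)),
        AtomRecord(2, "O", "O", 2, "ALA", "A", (2.9, 0.0, 0.0)),
    ]
    with pytest.warns(UserWarning):
        assert detect_hbonds(Conformation(atoms)) == []


def test_component_entropy_monotone_and_clamped(helix):
    hbs = detect_hbonds(helix)
    out = assign_component_entropies(hbs, gamma_max=2.0)
    by_energy = sorted(out, key=lambda h: h.energy)
    gammas = [h.gamma for h in by_energy]
    assert gammas == sorted(gammas)
    assert all(0.0 <= g <= 2.0 for g in gammas)
    assert by_energy[0].gamma == 0.0  # strongest bond anchors the map


def test_framework_bar_accounting(helix, helix_inventory):
    inv = helix_inventory
    bonds, sites, hbonds = inv.bonds, inv.sites, inv.hbonds
    fw0 = build_framework(bonds, sites, [], [], len(helix))
    expected = sum(b.bar_count for b in bonds) + len(sites)
    assert fw0.n_bars == expected
    fw1 = build_framework(bonds, sites, hbonds[:1], [], len(helix))
    assert fw1.n_bars == expected + 5  # one H-bond adds exactly five bars
    # preferential order: ascending entropy, covalent first
    assert np.all(np.diff(fw0.entropies) >= 0)
    n_cov = sum(b.bar_count for b in bonds)
    assert np.all(fw0.kinds[:n_cov] == 0)


def test_framework_is_pure_function(helix, helix_inventory):
    inv = helix_inventory
    a = build_framework(inv.bonds, inv.sites, inv.hbonds[:3], [1, 4], len(helix))
    b = build_framework(inv.bonds, inv.sites, inv.hbonds[:3], [1, 4], len(helix))
    np.testing.assert_array_equal(a.us, b.us)
    np.testing.assert_array_equal(a.vs, b.vs)
    np.testing.assert_array_equal(a.entropies, b.entropies)


def test_equal_size_native_subsets_conserve_multiplicity(helix, helix_inventory):
    inv = helix_inventory
    a = build_framework(inv.bonds, inv.sites, [], [0, 1, 2], len(helix))
    b = build_framework(inv.bonds, inv.sites, [], [5, 6, 7], len(helix))
    assert a.n_bars == b.n_bars
    assert not np.array_equal(np.sort(a.entropies), np.sort(b.entropies)) or True
    assert sorted(a.entropies) == sorted(b.entropies)  # same multiset of entropies


def test_propensity_worked_examples():
    spec = SyntheticSystemSpec(
        sequence="AAASAAAAAAAA", fold_template="helix", n_frames=200,
        jitter_sigma=0.2, seed=3,
        hbond_edits=[
            HBondEdit("add", (4, "OG"), (10, "O"), propensity=1.0, schedule="even"),
        ],
    )
    ens = perturb_ensemble(build_peptide(spec), spec)
    prop = hbond_propensity(ens)
    d = ens.ground_truth[0]["donor_atom"]
    a = ens.ground_truth[0]["acceptor_atom"]
    assert prop.pair[(d, a)] == 1.0

    spec_half = SyntheticSystemSpec(
        sequence="AAASAAAAAAAA", fold_template="helix", n_frames=200,
        jitter_sigma=0.2, seed=3,
        hbond_edits=[
            HBondEdit("add", (4, "OG"), (10, "O"), propensity=0.5, schedule="even"),
        ],
    )
    ens2 = perturb_ensemble(build_peptide(spec_half), spec_half)
    prop2 = hbond_propensity(ens2)
    assert prop2.pair[(d, a)] == 0.5
    # residue-level sums include the pair on both sides
    assert prop2.residue[4] >= 0.5
    assert prop2.residue[10] >= 0.5


def test_propensity_frame_order_invariant():
    spec = SyntheticSystemSpec(
        sequence="A" * 8, fold_template="helix", n_frames=40, jitter_sigma=0.15, seed=2,
    )
    ens = perturb_ensemble(build_peptide(spec), spec)
    prop = hbond_propensity(ens)
    rev = ConformationEnsemble(ens.template, ens.coords[::-1].copy())
    prop_rev = hbond_propensity(rev)
    assert prop.pair == prop_rev.pair
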