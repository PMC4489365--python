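"""Constraint inventory for the minimal distance constraint model (mDCM).

A conformation is converted into the three constraint classes the model
tracks:

* covalent bonds — 6 bars between atoms joined by a non-rotatable bond
  (peptide, double/aromatic, ring, or bond to hydrogen) and 5 bars for a
  rotatable single bond, leaving exactly the dihedral degree of freedom;
* hydrogen bonds / salt bridges — always 5 bars between the donor heavy
  atom and the acceptor, scored with a Mayo-style distance–angle energy and
  carrying a component entropy ``gamma`` that grows as the bond weakens;
* torsion sites — one bar across each rotatable bond with heavy atoms on
  both sides, in either a native (low entropy ``delta_nat``) or disordered
  (``delta_dis``) state.

Covalent chemistry is perceived from biotite's bundled Chemical Component
Dictionary, so all 20 standard amino acids are supported without local
templates.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc

from .structure_io import Conformation, ConformationEnsemble, to_atom_array

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

_SALT_DONORS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_SALT_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"),
                   ("GLU", "OE1"), ("GLU", "OE2")}


class UnknownResidueError(ValueError):
    pass


@dataclass(frozen=True)
class CovalentBond:
    """A covalent bond between atoms ``i`` and ``j`` (0-based indices)."""

    i: int
    j: int
    rotatable: bool

    @property
    def bar_count(self) -> int:
        return 5 if self.rotatable else 6


@dataclass(frozen=True)
class HydrogenBond:
    """A candidate hydrogen bond (donor heavy atom, its hydrogen, acceptor).

    ``energy`` is in kcal/mol (negative favourable); ``gamma`` is the pure-
    number component entropy per independent bar, assigned monotonically in
    energy by :func:`assign_component_entropies`.
    """

    donor: int
    hydrogen: int
    acceptor: int
    energy: float
    is_salt_bridge: bool = False
    gamma: float = 0.0

    bar_count = 5


@dataclass(frozen=True)
class TorsionSite:
    """A rotatable-bond dihedral tracked by the model."""

    central: tuple[int, int]
    dihedral: tuple[int, int, int, int]
    backbone_kind: str  # phi | psi | sidechain | other
    residue_index: int


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric gates and Mayo-style energy model for H-bond detection.

    Defaults: H···A <= 2.6 Å, D···A <= 3.6 Å, D–H···A angle >= 100 degrees,
    energy cutoff −0.1 kcal/mol, well depth 8 kcal/mol at R0 = 2.8 Å.
    """

    r_ha_max: float = 2.6
    r_da_max: float = 3.6
    angle_min_deg: float = 100.0
    energy_cutoff: float = -0.1
    well_depth: float = 8.0
    r0: float = 2.8

    def energy(self, d_da: float, cos_dha: float) -> float:
        ratio = self.r0 / d_da
        radial = self.well_depth * (5.0 * ratio ** 12 - 6.0 * ratio ** 10)
        return radial * cos_dha ** 2


@dataclass
class BodyBarFramework:
    """A body-bar multigraph in preferential insertion order.

    Bars are stored one array entry per unit of multiplicity, pre-sorted by
    ascending component entropy (covalent bars first, ties broken by
    inventory index).  ``kinds``: 0 covalent, 1 H-bond, 2 torsion.
    ``owners`` indexes into the corresponding inventory list.
    """

    n_vertices: int
    us: np.ndarray
    vs: np.ndarray
    kinds: np.ndarray
    owners: np.ndarray
    entropies: np.ndarray
    bonds: list[CovalentBond] | None = None
    hbonds: list[HydrogenBond] | None = None
    sites: list[TorsionSite] | None = None
    native_flags: np.ndarray | None = None  # per site, when sites given

    @property
    def n_bars(self) -> int:
        return int(self.us.shape[0])

    @classmethod
    def from_edges(cls, n_vertices: int, edges: Iterable[tuple]) -> "BodyBarFramework":
        """Generic framework from ``(u, v, multiplicity[, entropy])`` tuples."""
        us, vs, ent, owners = [], [], [], []
        for idx, e in enumerate(edges):
            u, v, mult = e[0], e[1], e[2]
            s = float(e[3]) if len(e) > 3 else 0.0
            if mult <= 0:
                raise ValueError("bar multiplicity must be positive")
            us.extend([u] * mult)
            vs.extend([v] * mult)
            ent.extend([s] * mult)
            owners.extend([idx] * mult)
        us = np.asarray(us, np.int64)
        vs = np.asarray(vs, np.int64)
        ent = np.asarray(ent, np.float64)
        owners = np.asarray(owners, np.int64)
        order = np.lexsort((owners, ent))
        return cls(
            n_vertices=n_vertices,
            us=us[order], vs=vs[order],
            kinds=np.zeros(us.shape[0], np.int64),
            owners=owners[order],
            entropies=ent[order],
        )


# --------------------------------------------------------------------------
# Covalent topology
# --------------------------------------------------------------------------

def _perceive_bonds(conformation: Conformation) -> np.ndarray:
    """(n_bonds, 3) array of [i, j, bond_type] from the CCD."""
    arr = to_atom_array(conformation)
    bond_list = struc.connect_via_residue_names(arr)
    return bond_list.as_array()


def detect_covalent_topology(conformation: Conformation) -> list[CovalentBond]:
    """Covalent bonds with rotatability assigned by chemistry.

    Non-rotatable: any bond involving hydrogen, peptide C–N bonds, bonds of
    order > 1 or aromatic bonds, and ring bonds (e.g. the proline ring, which
    removes the proline phi from the torsion inventory).
    """
    unknown = sorted({a.residue_name for a in conformation.atoms} - STANDARD_RESIDUES)
    if unknown:
        raise UnknownResidueError(f"unsupported residue name(s): {', '.join(unknown)}")
    raw = _perceive_bonds(conformation)
    atoms = conformation.atoms
    single = int(struc.BondType.SINGLE)

    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from((int(i), int(j)) for i, j, _ in raw)
    bridges = set(frozenset(e) for e in nx.bridges(g))

    bonds = []
    for i, j, btype in raw:
        i, j = int(i), int(j)
        ai, aj = atoms[i], atoms[j]
        rot = True
        if ai.element == "H" or aj.element == "H":
            rot = False
        elif int(btype) != single:
            rot = False  # double, triple or aromatic
        elif frozenset((i, j)) not in bridges:
            rot = False  # ring bond
        elif {ai.name, aj.name} == {"C", "N"} and ai.residue_index != aj.residue_index:
            rot = False  # peptide bond (partial double-bond character)
        bonds.append(CovalentBond(min(i, j), max(i, j), rot))
    bonds.sort(key=lambda b: (b.i, b.j))
    return bonds


def bond_graph(bonds: Sequence[CovalentBond], n_atoms: int) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from((b.i, b.j) for b in bonds)
    return g


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------

class _HBondContext:
    """Frame-independent donor/acceptor bookkeeping for fast per-frame detection."""

    def __init__(self, conformation: Conformation, criteria: HBondCriteria,
                 bonds: Sequence[CovalentBond] | None = None):
        self.criteria = criteria
        atoms = conformation.atoms
        self.atoms = atoms
        if bonds is None:
            bonds = detect_covalent_topology(conformation)
        g = bond_graph(bonds, len(atoms))
        self.graph = g
        attached_h: dict[int, list[int]] = {}
        for i, a in enumerate(atoms):
            if a.element in ("N", "O", "S"):
                hs = [n for n in g.neighbors(i) if atoms[n].element == "H"]
                if hs:
                    attached_h[i] = sorted(hs)
        self.donors = sorted(attached_h)
        self.donor_h = attached_h
        self.acceptors = [
            i for i, a in enumerate(atoms)
            if a.element in ("O", "S") or (a.element == "N" and i not in attached_h)
        ]
        # donor -> atoms within 3 covalent bonds (excluded as acceptors)
        self.excluded: dict[int, set[int]] = {
            d: set(nx.single_source_shortest_path_length(g, d, cutoff=3))
            for d in self.donors
        }

    def detect(self, coords: np.ndarray) -> list[HydrogenBond]:
        crit = self.criteria
        if not self.donors or not self.acceptors:
            return []
        acc = np.asarray(self.acceptors)
        tree = cKDTree(coords[acc])
        out = []
        for d in self.donors:
            for k in tree.query_ball_point(coords[d], crit.r_da_max):
                a = int(acc[k])
                if a in self.excluded[d]:
                    continue
                d_da = float(np.linalg.norm(coords[a] - coords[d]))
                if d_da > crit.r_da_max or d_da < 1e-6:
                    continue
                # the donor hydrogen closest to the acceptor
                best_h, best_ha = -1, np.inf
                for h in self.donor_h[d]:
                    d_ha = float(np.linalg.norm(coords[a] - coords[h]))
                    if d_ha < best_ha:
                        best_h, best_ha = h, d_ha
                if best_ha > crit.r_ha_max:
                    continue
                hd = coords[d] - coords[best_h]
                ha = coords[a] - coords[best_h]
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom < 1e-9:
                    continue
                cos_ang = float(np.dot(hd, ha) / denom)
                angle = np.degrees(np.arccos(np.clip(cos_ang, -1.0, 1.0)))
                if angle < crit.angle_min_deg:
                    continue
                energy = crit.energy(d_da, cos_ang)
                if energy > crit.energy_cutoff:
                    continue
                ad, aa = self.atoms[d], self.atoms[a]
                salt = (
                    ((ad.residue_name, ad.name) in _SALT_DONORS and (aa.residue_name, aa.name) in _SALT_ACCEPTORS)
                )
                out.append(HydrogenBond(d, best_h, a, energy, is_salt_bridge=salt))
        out.sort(key=lambda hb: (hb.donor, hb.acceptor))
        return out


def detect_hbonds(
    conformation: Conformation,
    criteria: HBondCriteria | None = None,
    bonds: Sequence[CovalentBond] | None = None,
) -> list[HydrogenBond]:
    """Hydrogen bonds / salt bridges satisfying the geometric and energy gates.

    Donors are N/O/S atoms carrying at least one covalently bound hydrogen;
    acceptors are any O/S plus nitrogens without hydrogens.  Pairs closer
    than 4 covalent bonds are excluded.  Emits a warning and returns an
    empty list if no donor carries a hydrogen.
    """
    criteria = criteria or HBondCriteria()
    ctx = _HBondContext(conformation, criteria, bonds)
    if not ctx.donors:
        warnings.warn("no donor hydrogens found; H-bond detection returns nothing")
        return []
    return ctx.detect(conformation.coords)


def assign_component_entropies(
    hbonds: Sequence[HydrogenBond],
    gamma_max: float = 2.0,
    energy_cutoff: float = -0.1,
) -> list[HydrogenBond]:
    """Map H-bond energies onto component entropies ``gamma`` in [0, gamma_max].

    The strongest bond in the inventory gets gamma = 0; a bond at the energy
    cutoff gets gamma_max; the map is affine and clamped, so weaker bonds
    always carry at least as much component entropy as stronger ones.
    """
    if not hbonds:
        return []
    e_min = min(hb.energy for hb in hbonds)
    span = energy_cutoff - e_min
    out = []
    for hb in hbonds:
        g = 0.0 if span <= 0 else gamma_max * (hb.energy - e_min) / span
        out.append(dataclasses.replace(hb, gamma=float(np.clip(g, 0.0, gamma_max))))
    return out


# --------------------------------------------------------------------------
# Torsion sites
# --------------------------------------------------------------------------

def enumerate_torsion_sites(
    bonds: Sequence[CovalentBond], conformation: Conformation
) -> list[TorsionSite]:
    """One torsion site per rotatable bond with heavy atoms on both sides.

    The dihedral's outer atoms are the lowest-index heavy neighbours on each
    side (deterministic); the torsion bar later connects those outer atoms.
    """
    atoms = conformation.atoms
    heavy_nbrs: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for b in bonds:
        if atoms[b.i].element != "H" and atoms[b.j].element != "H":
            heavy_nbrs[b.i].append(b.j)
            heavy_nbrs[b.j].append(b.i)
    sites = []
    for b in bonds:
        if not b.rotatable:
            continue
        left = sorted(n for n in heavy_nbrs[b.i] if n != b.j)
        right = sorted(n for n in heavy_nbrs[b.j] if n != b.i)
        if not left or not right:
            continue  # terminal rotor (e.g. methyl): free spin, no torsion constraint
        ai, aj = atoms[b.i], atoms[b.j]
        names = {ai.name, aj.name}
        if names == {"N", "CA"} and ai.residue_index == aj.residue_index:
            kind = "phi"
        elif names == {"CA", "C"} and ai.residue_index == aj.residue_index:
            kind = "psi"
        elif ai.name not in BACKBONE_NAMES or aj.name not in BACKBONE_NAMES:
            kind = "sidechain"
        else:
            kind = "other"
        sites.append(
            TorsionSite(
                central=(b.i, b.j),
                dihedral=(left[0], b.i, b.j, right[0]),
                backbone_kind=kind,
                residue_index=ai.residue_index if ai.name in ("N", "CA") else aj.residue_index,
            )
        )
    sites.sort(key=lambda s: s.central)
    return sites


# --------------------------------------------------------------------------
# Framework assembly
# --------------------------------------------------------------------------

def build_framework(
    bonds: Sequence[CovalentBond],
    sites: Sequence[TorsionSite],
    hbonds_present: Sequence[HydrogenBond],
    native_site_indices: Iterable[int],
    n_vertices: int,
    params=None,
) -> BodyBarFramework:
    """Assemble the body-bar framework for one constraint topology.

    Every covalent bond contributes ``bar_count`` bars at zero component
    entropy; every present H-bond contributes 5 bars at its ``gamma``;
    every torsion site contributes one bar between the dihedral's outer
    atoms, at ``delta_nat`` if the site index is in ``native_site_indices``
    and ``delta_dis`` otherwise (entropies from ``params``, default
    :class:`qsfr.thermo.DCMParameters`).  Bars come out sorted in
    preferential (ascending-entropy) order, covalent first, ties by
    inventory index.
    """
    if params is None:
        from .thermo import DCMParameters  # local import to avoid a cycle

        params = DCMParameters()
    native = np.zeros(len(sites), bool)
    for s in native_site_indices:
        if not 0 <= s < len(sites):
            raise ValueError(f"native site index {s} outside the torsion inventory")
        native[s] = True
    us, vs, kinds, owners, ent = [], [], [], [], []
    for idx, b in enumerate(bonds):
        for _ in range(b.bar_count):
            us.append(b.i); vs.append(b.j); kinds.append(0); owners.append(idx); ent.append(0.0)
    for idx, hb in enumerate(hbonds_present):
        for _ in range(5):
            us.append(hb.donor); vs.append(hb.acceptor); kinds.append(1); owners.append(idx)
            ent.append(hb.gamma)
    for idx, s in enumerate(sites):
        us.append(s.dihedral[0]); vs.append(s.dihedral[3]); kinds.append(2); owners.append(idx)
        ent.append(params.delta_nat if native[idx] else params.delta_dis)
    us = np.asarray(us, np.int64); vs = np.asarray(vs, np.int64)
    kinds = np.asarray(kinds, np.int64); owners = np.asarray(owners, np.int64)
    ent = np.asarray(ent, np.float64)
    noncov = (kinds != 0).astype(np.int64)
    order = np.lexsort((np.arange(us.shape[0]), noncov, ent))
    return BodyBarFramework(
        n_vertices=n_vertices,
        us=us[order], vs=vs[order], kinds=kinds[order], owners=owners[order],
        entropies=ent[order],
        bonds=list(bonds), hbonds=list(hbonds_present), sites=list(sites),
        native_flags=native,
    )


# --------------------------------------------------------------------------
# Ensemble H-bond propensity
# --------------------------------------------------------------------------

@dataclass
class HBondPropensityTable:
    """Fraction-of-frames occupancy per donor–acceptor pair and residue sums."""

    pair: dict[tuple[int, int], float]
    residue: dict[int, float]
    n_frames: int

    def to_frames(self):
        """(pair-level, residue-level) pandas DataFrames."""
        import pandas as pd

        pair_df = pd.DataFrame(
            [{"donor_atom": d, "acceptor_atom": a, "propensity": p}
             for (d, a), p in sorted(self.pair.items())]
        )
        res_df = pd.DataFrame(
            [{"residue_index": r, "propensity_sum": v} for r, v in sorted(self.residue.items())]
        )
        return pair_df, res_df


def hbond_propensity(
    ensemble: ConformationEnsemble,
    criteria: HBondCriteria | None = None,
) -> HBondPropensityTable:
    """Occupancy of every donor–acceptor pair over the ensemble frames.

    A pair present in every frame has propensity 1; in half the frames, 0.5.
    The residue-level value is the sum of the propensities of all pairs any
    of whose atoms (donor or acceptor) belong to that residue.
    """
    criteria = criteria or HBondCriteria()
    ctx = _HBondContext(ensemble.template, criteria)
    counts: dict[tuple[int, int], int] = {}
    n = len(ensemble)
    for f in range(n):
        for hb in ctx.detect(ensemble.coords[f]):
            key = (hb.donor, hb.acceptor)
            counts[key] = counts.get(key, 0) + 1
    pair = {k: c / n for k, c in counts.items()}
    residue: dict[int, float] = {}
    atoms = ensemble.template.atoms
    for (d, a), p in pair.items():
        for atom_idx in (d, a):
            r = atoms[atom_idx].residue_index
            residue[r] = residue.get(r, 0.0) + p
    return HBondPropensityTable(pair=pair, residue=residue, n_frames=n)
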