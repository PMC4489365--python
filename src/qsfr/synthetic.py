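"""Synthetic inputs for the whole pipeline — no downloads required.

This module generates every kind of input the analysis consumes:

* idealised peptides built from internal coordinates (standard bond
  lengths/angles; helix, hairpin or extended-coil backbone dihedrals) with
  explicit polar hydrogens (amide H, serine hydroxyl H) — supported
  residues: A, G, S, P;
* frame ensembles with isotropic Gaussian coordinate jitter and
  explicitly scheduled hydrogen-bond occupancy edits (each edited
  donor–acceptor pair is toggled per frame so its detected propensity
  matches a target);
* paired variant systems ("wild-type" vs "mutant") differing by a stated
  list of added/removed H-bonds, emulating germline/affinity-matured pairs;
* random connected body-bar multigraphs for rigidity-oracle tests;
* single-peak synthetic heat-capacity fitting targets.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import yaml

from .constraint_network import BodyBarFramework
from .structure_io import AtomRecord, Conformation, ConformationEnsemble
from .thermo import HeatCapacityCurve

# backbone geometry (Å, degrees): standard peptide values
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_B_CA_CB, _B_CB_OG, _B_OG_HG = 1.521, 1.417, 0.960
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.7
_A_CA_C_O, _A_N_CA_CB, _A_CA_CB_OG, _A_CB_OG_HG = 120.5, 110.5, 110.8, 108.5

_TEMPLATES = {
    "helix": (-57.0, -47.0),
    "hairpin": (-119.0, 113.0),
    "coil": (-75.0, 150.0),
}


@dataclass(frozen=True)
class HBondEdit:
    """A prescribed occupancy edit for one donor–acceptor pair.

    ``donor``/``acceptor`` are (residue_index, atom_name) pairs; the donor
    must carry a hydrogen.  ``propensity`` is the target fraction of frames
    in which the pair satisfies the H-bond criteria; ``schedule`` is
    "random" (Bernoulli per frame, matches the target within binomial
    error) or "even" (deterministic evenly spaced frames, matches exactly
    to within one frame).  ``action`` "add" creates a contact the base
    geometry lacks; "remove" suppresses one it has.
    """

    action: Literal["add", "remove"]
    donor: tuple[int, str]
    acceptor: tuple[int, str]
    propensity: float = 1.0
    schedule: Literal["random", "even"] = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.propensity <= 1.0:
            raise ValueError("target propensity must be in [0, 1]")


@dataclass
class SyntheticSystemSpec:
    """Recipe for one synthetic system (structure + ensemble)."""

    sequence: str
    fold_template: str = "helix"
    jitter_sigma: float = 0.25
    n_frames: int = 2000
    hbond_edits: list[HBondEdit] = field(default_factory=list)
    seed: int = 0
    n_substates: int = 8
    substate_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError("sequence must have at least 5 residues")
        if self.jitter_sigma < 0 or self.substate_amplitude < 0:
            raise ValueError("jitter_sigma and substate_amplitude must be non-negative")
        if self.n_substates < 1:
            raise ValueError("n_substates must be >= 1")
        if self.fold_template not in _TEMPLATES:
            raise ValueError(f"unknown fold template {self.fold_template!r}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSystemSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        edits = [HBondEdit(
            action=e["action"],
            donor=(int(e["donor"][0]), str(e["donor"][1])),
            acceptor=(int(e["acceptor"][0]), str(e["acceptor"][1])),
            propensity=float(e.get("propensity", 1.0)),
            schedule=e.get("schedule", "random"),
        ) for e in raw.pop("hbond_edits", [])]
        return cls(hbond_edits=edits, **raw)


# --------------------------------------------------------------------------
# peptide construction (NeRF internal-coordinate chain extension)
# --------------------------------------------------------------------------


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and dihedral(a,b,c,d)."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_dihedrals(n_res: int, template: str) -> tuple[np.ndarray, np.ndarray]:
    phi = np.full(n_res, _TEMPLATES[template][0])
    psi = np.full(n_res, _TEMPLATES[template][1])
    if template == "hairpin":
        # two-residue turn in the middle of the strand pair
        t1 = n_res // 2 - 1
        phi[t1], psi[t1] = 60.0, 30.0
        phi[t1 + 1], psi[t1 + 1] = 90.0, 0.0
    return phi, psi


_SUPPORTED = {"A": "ALA", "G": "GLY", "S": "SER", "P": "PRO"}


def build_peptide(spec: SyntheticSystemSpec) -> Conformation:
    """All-atom peptide (polar hydrogens only) from internal coordinates.

    Backbone dihedrals come from the fold template (helix −57/−47; hairpin
    strands −119/113 with a canonical two-residue turn; extended coil
    −75/150); bond lengths and angles are standard.  Amide hydrogens are
    placed on the N–H bisector in the peptide plane (trans to the carbonyl
    oxygen); serine hydroxyls get their HG.  Deterministic given the spec.
    """
    seq = spec.sequence.upper()
    bad = sorted(set(seq) - set(_SUPPORTED))
    if bad:
        raise ValueError(f"unsupported residue letter(s): {', '.join(bad)}")
    n_res = len(seq)
    phi, psi = _backbone_dihedrals(n_res, spec.fold_template)

    # backbone trace
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])

    atoms: list[AtomRecord] = []
    serial = 1

    def add(name: str, element: str, res_i: int, pos: np.ndarray) -> None:
        nonlocal serial
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element,
            residue_index=res_i + 1, residue_name=_SUPPORTED[seq[res_i]],
            chain_id="A", position=tuple(float(x) for x in pos),
        ))
        serial += 1

    for i in range(n_res):
        res = seq[i]
        add("N", "N", i, N[i])
        add("CA", "C", i, CA[i])
        add("C", "C", i, C[i])
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        add("O", "O", i, O)
        if i == n_res - 1:
            add("OXT", "O", i, _nerf(N[i], CA[i], C[i], 1.25, 117.0, psi[i]))
        if res != "G":
            CB = _nerf(N[i], C[i], CA[i], _B_CA_CB, _A_N_CA_CB, 122.5)
            add("CB", "C", i, CB)
            if res == "S":
                OG = _nerf(N[i], CA[i], CB, _B_CB_OG, _A_CA_CB_OG, -60.0)
                add("OG", "O", i, OG)
                add("HG", "H", i, _nerf(CA[i], CB, OG, _B_OG_HG, _A_CB_OG_HG, 180.0))
            elif res == "P":
                CG = _nerf(N[i], CA[i], CB, 1.495, 104.5, 28.5)
                add("CG", "C", i, CG)
                add("CD", "C", i, _nerf(CA[i], CB, CG, 1.507, 106.1, -40.0))
        if res != "P":
            # amide H on the in-plane bisector, trans to the carbonyl oxygen
            if i > 0:
                prev_c = C[i - 1]
            else:
                prev_c = _nerf(C[0], CA[0], N[0], _B_C_N, _A_C_N_CA, phi[0])
            u1 = N[i] - prev_c
            u2 = N[i] - CA[i]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            add("H", "H", i, N[i] + _B_N_H * u / np.linalg.norm(u))

    return Conformation(atoms, identifier=f"{spec.fold_template}-{seq}")


# --------------------------------------------------------------------------
# ensembles with controlled H-bond occupancy
# --------------------------------------------------------------------------


def _find_atom(conf: Conformation, residue_index: int, name: str) -> int:
    for i, a in enumerate(conf.atoms):
        if a.residue_index == residue_index and a.name == name:
            return i
    raise KeyError(f"atom {name} of residue {residue_index} not found")


def _donor_hydrogen(conf: Conformation, donor: int) -> int:
    coords = conf.coords
    best, best_d = -1, 1.3
    for i, a in enumerate(conf.atoms):
        if a.element == "H":
            d = float(np.linalg.norm(coords[i] - coords[donor]))
            if d < best_d:
                best, best_d = i, d
    if best < 0:
        raise ValueError(f"donor atom {donor} carries no hydrogen")
    return best


def _edit_schedule(edit: HBondEdit, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    p = edit.propensity
    if edit.schedule == "even":
        idx = np.arange(n_frames)
        return np.floor((idx + 1) * p) > np.floor(idx * p)
    return rng.random(n_frames) < p


def perturb_ensemble(base: Conformation, spec: SyntheticSystemSpec) -> ConformationEnsemble:
    """Jittered frames with the spec's H-bond edits enforced per frame.

    The ensemble emulates the cluster structure of a molecular-dynamics
    trajectory: frames hop between ``n_substates`` metastable substates
    (fixed per-atom offset fields of amplitude ``substate_amplitude``,
    occupancies drawn from a Dirichlet so cluster sizes are comparable but
    uneven), with isotropic Gaussian noise (``jitter_sigma`` per
    coordinate) on top.  For every edit, frames scheduled "present" get the
    donor hydrogen re-placed on the donor→acceptor line (the acceptor is
    pulled to 2.9 Å if it sits beyond the distance gate), guaranteeing
    detection; frames scheduled "absent" get the hydrogen swung to the far
    side of the donor, guaranteeing rejection by the angular gate.
    """
    if spec.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(spec.seed)
    base_xyz = base.coords
    n_atoms = base_xyz.shape[0]
    coords = base_xyz[None, :, :] + rng.normal(
        scale=spec.jitter_sigma, size=(spec.n_frames, n_atoms, 3)
    )
    if spec.n_substates > 1 and spec.substate_amplitude > 0:
        offsets = rng.normal(
            scale=spec.substate_amplitude, size=(spec.n_substates, n_atoms, 3)
        )
        occupancy = rng.dirichlet(np.full(spec.n_substates, 3.0))
        membership = rng.choice(spec.n_substates, size=spec.n_frames, p=occupancy)
        coords += offsets[membership]
    truth = []
    for edit in spec.hbond_edits:
        d = _find_atom(base, *edit.donor)
        a = _find_atom(base, *edit.acceptor)
        h = _donor_hydrogen(base, d)
        present = _edit_schedule(edit, spec.n_frames, rng)
        for f in range(spec.n_frames):
            dv = coords[f, a] - coords[f, d]
            dist = float(np.linalg.norm(dv))
            if dist < 1e-6:
                dv, dist = np.array([1.0, 0.0, 0.0]), 1.0
            unit = dv / dist
            if present[f]:
                if dist > 3.3 or dist < 2.7:
                    coords[f, a] = coords[f, d] + 2.9 * unit
                    unit = (coords[f, a] - coords[f, d]) / 2.9
                coords[f, h] = coords[f, d] + _B_N_H * unit
            else:
                coords[f, h] = coords[f, d] - _B_N_H * unit
        truth.append({
            "action": edit.action,
            "donor_atom": d, "hydrogen_atom": h, "acceptor_atom": a,
            "target_propensity": edit.propensity,
            "scheduled_fraction": float(present.mean()),
        })
    ens = ConformationEnsemble(base, coords)
    ens.ground_truth = truth  # sidecar for tests; serialised by the pipeline
    return ens


def make_variant_pair(
    base_spec: SyntheticSystemSpec, edits: Sequence[HBondEdit]
) -> tuple[ConformationEnsemble, ConformationEnsemble, list[dict]]:
    """A wild-type/mutant-style ensemble pair differing by ``edits``.

    System A is the base spec as-is; system B applies the H-bond edits.
    The two ensembles use distinct seeds derived from the base seed, and
    the ground-truth edit list is returned for assertions.
    """
    spec_a = replace(base_spec, hbond_edits=list(base_spec.hbond_edits))
    spec_b = replace(
        base_spec,
        hbond_edits=list(base_spec.hbond_edits) + list(edits),
        seed=base_spec.seed + 1,
    )
    base_a = build_peptide(spec_a)
    base_b = build_peptide(spec_b)
    ens_a = perturb_ensemble(base_a, spec_a)
    ens_b = perturb_ensemble(base_b, spec_b)
    return ens_a, ens_b, list(getattr(ens_b, "ground_truth", []))


# --------------------------------------------------------------------------
# random body-bar frameworks and Cp targets
# --------------------------------------------------------------------------


def random_bodybar_graph(
    n_vertices: int,
    n_extra_edges: int,
    multiplicity_range: tuple[int, int] = (1, 6),
    seed: int = 0,
    random_entropies: bool = False,
) -> BodyBarFramework:
    """Connected random body-bar multigraph (spanning tree first).

    Tree edges and ``n_extra_edges`` additional random edges each carry a
    uniform random multiplicity from ``multiplicity_range``.  With
    ``random_entropies`` every edge gets a uniform [0, 2] component entropy
    (for insertion-order experiments); otherwise all entropies are 0.
    """
    if n_vertices < 1:
        raise ValueError("need at least one vertex")
    rng = np.random.default_rng(seed)
    lo, hi = multiplicity_range
    edges = []
    for v in range(1, n_vertices):
        u = int(rng.integers(0, v))
        edges.append((u, v))
    for _ in range(n_extra_edges):
        u = int(rng.integers(0, n_vertices))
        v = int(rng.integers(0, n_vertices))
        if u == v:
            v = (v + 1) % n_vertices
        if n_vertices > 1:
            edges.append((min(u, v), max(u, v)))
    full = []
    for (u, v) in edges:
        mult = int(rng.integers(lo, hi + 1))
        ent = float(rng.uniform(0.0, 2.0)) if random_entropies else 0.0
        full.append((u, v, mult, ent))
    return BodyBarFramework.from_edges(n_vertices, full)


def synthetic_cp_target(
    t_m: float, width: float, n_points: int = 201, shape: str = "gaussian"
) -> HeatCapacityCurve:
    """Single-peak heat-capacity fitting target with its maximum exactly at t_m.

    ``shape`` is "gaussian" or "sech2" (the two-state van 't Hoff peak
    shape in the narrow-transition limit); the grid is symmetric about t_m
    so the argmax is exact.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if n_points % 2 == 0:
        n_points += 1
    T = np.linspace(t_m - 4 * width, t_m + 4 * width, n_points)
    x = (T - t_m) / width
    if shape == "gaussian":
        cp = np.exp(-0.5 * x**2)
    elif shape == "sech2":
        cp = 1.0 / np.cosh(x) ** 2
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return HeatCapacityCurve(temperature=T, cp=cp)
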