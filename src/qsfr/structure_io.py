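"""All-atom structure and ensemble I/O, superposition, and fluctuation analysis.

Structures are plain fixed-column PDB (v3.3); multi-frame ensembles are
multi-model PDB files (``MODEL``/``ENDMDL``).  Parsing and writing is done
through :mod:`biotite`; this module wraps it in small immutable containers
(:class:`AtomRecord`, :class:`Conformation`, :class:`ConformationEnsemble`)
that the rest of the package consumes.

Residue indices are re-assigned on read as a global, sequential, 1-based
counter in file order (insertion codes ignored), so that every downstream
table can key on a single integer.  Hydrogens are never built here: a
structure used for hydrogen-bond detection must already contain its polar
hydrogens.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus Cartesian position in Å."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"serial must be positive, got {self.serial}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class Conformation:
    """An ordered collection of atoms forming one model of a structure."""

    atoms: list[AtomRecord]
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Conformation needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a conformation")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    @property
    def n_residues(self) -> int:
        return len({(a.chain_id, a.residue_index) for a in self.atoms})

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=np.int64)

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "Conformation":
        """Copy of this conformation with replaced coordinates."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [
            dataclasses.replace(a, position=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return Conformation(atoms, identifier if identifier is not None else self.identifier)

    def select(self, *, names: Iterable[str] | None = None) -> np.ndarray:
        """0-based indices of atoms whose name is in ``names`` (all if None)."""
        if names is None:
            return np.arange(len(self.atoms))
        wanted = set(names)
        return np.array([i for i, a in enumerate(self.atoms) if a.name in wanted], dtype=np.int64)


@dataclass
class ConformationEnsemble:
    """Frames sharing one atom inventory; coordinates stored as one array.

    ``template`` supplies atom identities; ``coords`` has shape
    (n_frames, n_atoms, 3).  Optional ``frame_weights`` must be non-negative
    and sum to 1.
    """

    template: Conformation
    coords: np.ndarray
    frame_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.template) or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, {len(self.template)}, 3), got {self.coords.shape}"
            )
        if self.frame_weights is not None:
            w = np.asarray(self.frame_weights, dtype=np.float64)
            if w.shape != (self.coords.shape[0],):
                raise ValueError("frame_weights length must equal the frame count")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("frame_weights must be non-negative and sum to 1")
            self.frame_weights = w

    @classmethod
    def from_frames(cls, frames: Sequence[Conformation], frame_weights=None) -> "ConformationEnsemble":
        if not frames:
            raise ValueError("an ensemble needs at least one frame")
        names0 = frames[0].atom_names()
        for k, f in enumerate(frames[1:], start=2):
            if f.atom_names() != names0:
                raise ValueError(f"frame {k} does not share the atom ordering of frame 1")
        coords = np.stack([f.coords for f in frames])
        return cls(frames[0], coords, frame_weights)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> Conformation:
        return self.template.with_coords(self.coords[i], identifier=f"{self.template.identifier}/frame{i}")

    @property
    def frames(self) -> Iterator[Conformation]:
        return (self[i] for i in range(len(self)))


# --------------------------------------------------------------------------
# PDB reading / writing
# --------------------------------------------------------------------------

def _diagnose_pdb(path: Path) -> str:
    """Best-effort location of the first malformed ATOM/HETATM line."""
    try:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    return f" (first malformed coordinate record at line {lineno})"
        return ""
    except OSError:
        return ""


def _atom_array_to_conformation(arr: "struc.AtomArray", identifier: str) -> Conformation:
    atoms = []
    res_counter = 0
    prev_key = None
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), str(getattr(arr, "ins_code", [""] * arr.array_length())[i]))
        if key != prev_key:
            res_counter += 1
            prev_key = key
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_index=res_counter,
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                position=tuple(float(x) for x in arr.coord[i]),
            )
        )
    return Conformation(atoms, identifier)


def to_atom_array(conformation: Conformation) -> "struc.AtomArray":
    """Convert to a biotite ``AtomArray`` (used for bond perception and writing)."""
    n = len(conformation)
    arr = struc.AtomArray(n)
    arr.coord = conformation.coords
    arr.atom_name = np.array(conformation.atom_names(), dtype="U6")
    arr.res_name = np.array([a.residue_name for a in conformation.atoms], dtype="U5")
    arr.res_id = np.array([a.residue_index for a in conformation.atoms], dtype=int)
    arr.chain_id = np.array([a.chain_id for a in conformation.atoms], dtype="U4")
    arr.element = np.array([a.element for a in conformation.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def read_structure(path, model_index: int | None = None) -> Conformation:
    """Read one model of a PDB file.

    ``model_index`` is 1-based; ``None`` selects the first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"cannot parse {path}{_diagnose_pdb(path)}: {exc}") from exc
    if n_models == 0:
        raise PDBParseError(f"{path} contains no ATOM records{_diagnose_pdb(path)}")
    model = 1 if model_index is None else model_index
    if not 1 <= model <= n_models:
        raise PDBParseError(f"{path} has {n_models} model(s); model_index={model_index} is out of range")
    try:
        arr = pdb.get_structure(model=model)
    except Exception as exc:
        raise PDBParseError(f"cannot parse {path}{_diagnose_pdb(path)}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"{path} model {model} is empty{_diagnose_pdb(path)}")
    return _atom_array_to_conformation(arr, identifier=path.stem)


def write_structure(conformation: Conformation, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(conformation))
    pdb.write(str(path))


def read_ensemble(path, frame_weights=None) -> ConformationEnsemble:
    """Read a multi-model PDB as an ensemble (all models, file order)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise PDBParseError(f"cannot parse {path}{_diagnose_pdb(path)}: {exc}") from exc
    if n_models == 0:
        raise PDBParseError(f"{path} contains no ATOM records")
    template = _atom_array_to_conformation(pdb.get_structure(model=1), identifier=path.stem)
    stack = pdb.get_structure()
    coords = stack.coord if stack.coord.ndim == 3 else stack.coord[None, :, :]
    return ConformationEnsemble(template, coords, frame_weights)


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    n_frames, n_atoms = ensemble.coords.shape[:2]
    arr = to_atom_array(ensemble.template)
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = ensemble.coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# Superposition and fluctuations
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point sets (no reflection).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to ``reference``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rmsd2 = (np.sum(P * P) + np.sum(Q * Q) - 2.0 * (S[0] + S[1] + d * S[2])) / n
    rmsd = float(np.sqrt(max(rmsd2, 0.0)))
    t = cr - R @ cm
    return R, t, rmsd


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Post-superposition RMSD without materialising the rotated coordinates."""
    return kabsch(mobile, reference)[2]


def superpose(
    mobile: Conformation, reference: Conformation, selection: Sequence[int] | None = None
) -> tuple[Conformation, float]:
    """Optimally superpose ``mobile`` onto ``reference`` over ``selection``.

    ``selection`` holds 0-based atom indices valid in both conformations
    (all atoms if None) and must contain at least 3 atoms, otherwise the
    rotation is underdetermined.  The full mobile conformation is
    transformed; the returned RMSD is evaluated over the selection.
    """
    sel = np.arange(len(mobile)) if selection is None else np.asarray(list(selection), dtype=np.int64)
    if sel.size < 3:
        raise ValueError(f"selection must contain at least 3 atoms, got {sel.size}")
    mc = mobile.coords
    rc = reference.coords
    R, t, rmsd = kabsch(mc[sel], rc[sel])
    moved = mobile.with_coords(mc @ R.T + t)
    return moved, rmsd


def _iterative_mean_fit(
    coords: np.ndarray, fit_sel: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> np.ndarray:
    """Superpose every frame onto the evolving ensemble mean; return fitted coords."""
    fitted = coords.copy()
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for i in range(fitted.shape[0]):
            R, t, _ = kabsch(fitted[i, fit_sel], mean[fit_sel])
            fitted[i] = fitted[i] @ R.T + t
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return fitted


def compute_rmsf(
    ensemble: ConformationEnsemble,
    selection: Sequence[int] | None = None,
    fit_selection: Sequence[int] | None = None,
    fit: bool = True,
):
    """Per-residue RMSF (Å) about the ensemble mean.

    Frames are iteratively superposed onto the ensemble mean over
    ``fit_selection`` (default: Cα atoms; set ``fit=False`` to skip fitting).
    ``selection`` picks the atoms averaged within each residue (default Cα).
    Returns a ``pandas.DataFrame`` with columns ``residue_index``, ``chain``,
    ``rmsf``.
    """
    import pandas as pd

    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    tmpl = ensemble.template
    ca = tmpl.select(names=["CA"])
    sel = ca if selection is None else np.asarray(list(selection), dtype=np.int64)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if fit:
        fsel = ca if fit_selection is None else np.asarray(list(fit_selection), dtype=np.int64)
        coords = _iterative_mean_fit(ensemble.coords, fsel)
    else:
        coords = ensemble.coords
    mean = coords.mean(axis=0)
    msd = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)  # per atom
    per_atom = np.sqrt(msd)
    rows: dict[tuple[int, str], list[float]] = {}
    for i in sel:
        a = tmpl.atoms[int(i)]
        rows.setdefault((a.residue_index, a.chain_id), []).append(per_atom[int(i)])
    data = [
        {"residue_index": ri, "chain": ch, "rmsf": float(np.mean(v))}
        for (ri, ch), v in sorted(rows.items())
    ]
    return pd.DataFrame(data)
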