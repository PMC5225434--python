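"""Conformational-ensemble container, I/O, atom selection and superposition.

A :class:`TrajectoryEnsemble` is an ordered stack of frames sharing one atom
topology, with Cartesian coordinates in Å. Everything downstream (RMSF,
covariance analysis, cross-correlation, hydrogen-bond occupancy) consumes this
container, so fluctuation statistics are computed after rigid-body motion has
been removed by :func:`kabsch_superpose` or :func:`iterative_mean_fit`.

Internal units are Å for length and ns for time throughout the package.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFitError,
    ParseError,
    SelectionError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "Atom",
    "TrajectoryEnsemble",
    "AtomSelection",
    "SuperpositionResult",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "select_atoms",
    "rmsd",
    "kabsch_superpose",
    "iterative_mean_fit",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    """Atom metadata (coordinates live in the ensemble, not here).

    ``residue_name`` follows PDB conventions ("ASN", "HOH", or a ligand
    het-code); ``name`` is the PDB atom name ("CA", "OD1", "N4").
    """

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    element: str = ""

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``ASN33-OD1``."""
        return f"{self.residue_name}{self.residue_number}-{self.name}"


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of Cartesian coordinates over a shared atom topology.

    Parameters
    ----------
    atoms
        Topology shared by every frame.
    coordinates
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    frame_times
        Optional per-frame times in ns.
    """

    atoms: tuple[Atom, ...]
    coordinates: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError(
                f"coordinates must have shape (frames, atoms, 3), got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise ValidationError("ensemble must contain at least one frame")
        if coords.shape[1] != len(self.atoms):
            raise TopologyError(
                f"coordinate array has {coords.shape[1]} atoms but topology has "
                f"{len(self.atoms)}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates contain non-finite values")
        self.coordinates = coords
        if self.frame_times is not None:
            times = np.asarray(self.frame_times, dtype=float)
            if times.shape != (coords.shape[0],):
                raise ValidationError("frame_times length must equal frame count")
            self.frame_times = times

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, index: int) -> np.ndarray:
        """Coordinates of one frame, shape ``(n_atoms, 3)``."""
        return self.coordinates[index]

    def with_coordinates(self, coordinates: np.ndarray) -> "TrajectoryEnsemble":
        """New ensemble sharing this topology with replaced coordinates."""
        return replace(self, coordinates=coordinates)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique indices into a :class:`TrajectoryEnsemble`'s atoms."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if list(idx) != sorted(set(idx)):
            raise SelectionError("selection indices must be unique and ascending")
        if idx and idx[0] < 0:
            raise SelectionError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class SuperpositionResult:
    """Outcome of rigidly fitting every frame onto a reference.

    ``reference_frame`` is the index of the reference frame, or ``-1`` when the
    reference was an external structure (e.g. the converged mean of
    :func:`iterative_mean_fit`).
    """

    rotated_trajectory: TrajectoryEnsemble
    per_frame_rmsd: np.ndarray
    reference_frame: int
    mean_structure: np.ndarray | None = None
    n_iterations: int = 1
    converged: bool = True


# ---------------------------------------------------------------------------
# PDB I/O (Bio.PDB does the parsing; we flatten models into the ensemble)
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path: str) -> TrajectoryEnsemble:
    """Read a (multi-)MODEL PDB file into an ensemble, one frame per MODEL.

    HETATM records (ligands, waters) are retained under their het-code residue
    name. For alternate locations the highest-occupancy conformer is kept
    (ties: first encountered). Waters and ions parse like any other residue.

    Raises
    ------
    ParseError
        Malformed records (the underlying parser names the line).
    TopologyError
        MODELs disagree in atom count or identity.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("ens", path)
    except PDBConstructionException as exc:
        raise ParseError(f"failed to parse PDB file {path!r}: {exc}") from exc

    frames: list[np.ndarray] = []
    topologies: list[tuple[Atom, ...]] = []
    for model in structure:
        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    # Disordered atoms: Bio.PDB's selected child is the
                    # highest-occupancy altloc (first on ties).
                    if atom.is_disordered():
                        atom = atom.selected_child
                    atoms.append(
                        Atom(
                            serial=int(atom.serial_number),
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            residue_number=int(residue.id[1]),
                            chain_id=str(chain.id),
                            element=(atom.element or "").strip(),
                        )
                    )
                    coords.append(np.asarray(atom.get_coord(), dtype=float))
        topologies.append(tuple(atoms))
        frames.append(np.asarray(coords, dtype=float))

    if not frames:
        raise ParseError(f"no models found in PDB file {path!r}")

    ref = topologies[0]
    for m, topo in enumerate(topologies[1:], start=2):
        if len(topo) != len(ref):
            raise TopologyError(
                f"MODEL {m} has {len(topo)} atoms but MODEL 1 has {len(ref)}"
            )
        for a, b in zip(ref, topo):
            if (a.name, a.residue_name, a.residue_number, a.chain_id) != (
                b.name,
                b.residue_name,
                b.residue_number,
                b.chain_id,
            ):
                raise TopologyError(
                    f"MODEL {m} atom {b.serial} ({b.label}) does not match "
                    f"MODEL 1 atom {a.serial} ({a.label})"
                )

    return TrajectoryEnsemble(atoms=ref, coordinates=np.stack(frames))


def write_multimodel_pdb(traj: TrajectoryEnsemble, path: str) -> None:
    """Write an ensemble as a minimal multi-MODEL PDB (no headers)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(traj.atoms):
                x, y, z = traj.coordinates[f, i]
                record = "HETATM" if atom.residue_name in _HET_RESNAMES or len(atom.residue_name) > 3 else "ATOM  "
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{atom.serial:5d} {name:<4s}{atom.residue_name:>4s} "
                    f"{atom.chain_id:1s}{atom.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


_HET_RESNAMES = frozenset({"HOH", "WAT", "SOL", "LIG", "UNL", "UNK", "NA", "CL"})

# Residue names treated as protein by the selection keyword `protein`.
_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE".split()
)


# ---------------------------------------------------------------------------
# XYZ trajectory I/O
# ---------------------------------------------------------------------------
# Frame block: atom-count line, comment line, then one "name x y z" row per
# atom at fixed 4-decimal precision. Topology (residues, serials) travels
# separately, so the format round-trips exactly at that precision.

def write_xyz_trajectory(traj: TrajectoryEnsemble, path: str) -> None:
    """Write frames as XYZ blocks (4-decimal precision, Å)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            t = traj.frame_times[f] if traj.frame_times is not None else f
            fh.write(f"frame {f} t={t:g}\n")
            for i, atom in enumerate(traj.atoms):
                x, y, z = traj.coordinates[f, i]
                fh.write(f"{atom.name} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz_trajectory(path: str, topology: Sequence[Atom]) -> TrajectoryEnsemble:
    """Read an XYZ trajectory written by :func:`write_xyz_trajectory`.

    The supplied ``topology`` provides residue/serial metadata the XYZ format
    does not carry; each frame block must match its length.
    """
    topology = tuple(topology)
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"empty XYZ file {path!r}")

    pos = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"line {pos + 1}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if count != len(topology):
            raise TopologyError(
                f"line {pos + 1}: frame has {count} atoms but topology has "
                f"{len(topology)}"
            )
        if pos + 1 + count >= n_lines + 1:
            raise ParseError(f"line {pos + 1}: truncated frame block")
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise ParseError(f"line {pos + 1}: truncated frame block")
        coords = np.empty((count, 3))
        for i, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise ParseError(
                    f"line {pos + 3 + i}: expected 'name x y z', got {row!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"line {pos + 3 + i}: malformed coordinate in {row!r}"
                ) from exc
            if not all(math.isfinite(v) for v in xyz):
                raise ValidationError(
                    f"line {pos + 3 + i}: non-finite coordinate in {row!r}"
                )
            coords[i] = xyz
        frames.append(coords)
        pos += 2 + count

    return TrajectoryEnsemble(atoms=topology, coordinates=np.stack(frames))


# ---------------------------------------------------------------------------
# Atom selection mini-grammar
# ---------------------------------------------------------------------------
# query     := clause ("and" clause)*
# clause    := "name" names | "resname" names | "chain" ids
#            | "resid" ranges | "protein" | "water" | "hetero" | "all"
# names/ids := whitespace- or comma-separated tokens
# ranges    := N | N-M, comma-separated

_KEYWORDS = {"name", "resname", "chain", "resid", "protein", "water", "hetero", "all"}
_WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})


def _parse_resid_ranges(tokens: list[str], query: str) -> list[tuple[int, int]]:
    ranges = []
    for tok in tokens:
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", tok)
        if not m:
            raise SelectionError(f"bad resid token {tok!r} in query {query!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(f"empty resid range {tok!r} in query {query!r}")
        ranges.append((lo, hi))
    return ranges


def select_atoms(traj: TrajectoryEnsemble, query: str) -> AtomSelection:
    """Select atoms with a small boolean-AND query language.

    Supported clauses: ``name CA``, ``resname TH2``, ``chain A``,
    ``resid 23-29`` (single numbers and comma lists allowed), ``protein``,
    ``water``, ``hetero``, ``all``. Clauses are joined with ``and``. Values may
    be comma- or space-separated (``name CA,CB``). The selection is
    deterministic and ordered by atom index; an empty result is allowed but
    warned about.
    """
    if not query or not query.strip():
        raise SelectionError("empty selection query")
    # split on 'and' at word boundaries
    parts = re.split(r"\band\b", query.strip())
    mask = np.ones(traj.n_atoms, dtype=bool)
    atoms = traj.atoms
    for part in parts:
        tokens = part.replace(",", " ").split()
        if not tokens:
            raise SelectionError(f"empty clause in query {query!r}")
        key, args = tokens[0].lower(), tokens[1:]
        if key not in _KEYWORDS:
            raise SelectionError(f"unknown keyword {tokens[0]!r} in query {query!r}")
        if key in {"protein", "water", "hetero", "all"} and args:
            raise SelectionError(f"keyword {key!r} takes no arguments")
        if key in {"name", "resname", "chain"} and not args:
            raise SelectionError(f"keyword {key!r} needs at least one value")
        if key == "name":
            wanted = {a.upper() for a in args}
            clause = np.array([a.name.upper() in wanted for a in atoms])
        elif key == "resname":
            wanted = {a.upper() for a in args}
            clause = np.array([a.residue_name.upper() in wanted for a in atoms])
        elif key == "chain":
            wanted = set(args)
            clause = np.array([a.chain_id in wanted for a in atoms])
        elif key == "resid":
            ranges = _parse_resid_ranges(args, query)
            clause = np.array(
                [any(lo <= a.residue_number <= hi for lo, hi in ranges) for a in atoms]
            )
        elif key == "protein":
            clause = np.array([a.residue_name.upper() in _AMINO_ACIDS for a in atoms])
        elif key == "water":
            clause = np.array([a.residue_name.upper() in _WATER_RESNAMES for a in atoms])
        elif key == "hetero":
            clause = np.array(
                [
                    a.residue_name.upper() not in _AMINO_ACIDS
                    and a.residue_name.upper() not in _WATER_RESNAMES
                    for a in atoms
                ]
            )
        else:  # all
            clause = np.ones(traj.n_atoms, dtype=bool)
        mask &= clause
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    if not indices:
        warnings.warn(f"selection {query!r} matched no atoms", stacklevel=2)
    return AtomSelection(indices=indices)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two coordinate sets of equal shape, Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _check_fit_points(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-8:
        raise DegenerateFitError("fit atoms are (near-)collinear")


def _kabsch_rotations(mobile_centered: np.ndarray, ref_centered: np.ndarray) -> np.ndarray:
    """Batched Kabsch: optimal proper rotations R (F, 3, 3) minimizing
    ||mobile @ R.T - ref|| per frame, via SVD of the cross-covariance."""
    h = np.einsum("fma,mb->fab", mobile_centered, ref_centered)  # (F, 3, 3)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fab->fba", vt) @ np.einsum("fab->fba", u))
    # flip the smallest singular direction where the solution is improper
    d = np.ones((h.shape[0], 3))
    d[:, 2] = np.sign(det)
    return np.einsum("fba,fb,fcb->fac", vt, d, u)


def kabsch_superpose(
    traj: TrajectoryEnsemble,
    fit_selection: AtomSelection,
    reference: int | np.ndarray = 0,
) -> SuperpositionResult:
    """Least-squares rigid superposition of every frame onto a reference.

    The optimal proper rotation (determinant +1) is the Kabsch solution,
    computed over ``fit_selection`` and applied to *all* atoms of each frame.

    ``reference`` is a frame index, or an external ``(n_fit, 3)`` coordinate
    array over the fit selection.
    """
    idx = fit_selection.as_array()
    if isinstance(reference, (int, np.integer)):
        ref_fit = traj.coordinates[int(reference), idx]
        ref_frame = int(reference)
    else:
        ref_fit = np.asarray(reference, dtype=float)
        if ref_fit.shape != (len(idx), 3):
            raise ValidationError(
                f"external reference must have shape ({len(idx)}, 3), got {ref_fit.shape}"
            )
        ref_frame = -1
    _check_fit_points(ref_fit)

    ref_centroid = ref_fit.mean(axis=0)
    ref_centered = ref_fit - ref_centroid
    mob_centroids = traj.coordinates[:, idx].mean(axis=1)  # (F, 3)
    mobile_centered = traj.coordinates[:, idx] - mob_centroids[:, None, :]
    rots = _kabsch_rotations(mobile_centered, ref_centered)
    all_centered = traj.coordinates - mob_centroids[:, None, :]
    out = np.einsum("fma,fba->fmb", all_centered, rots) + ref_centroid
    per_frame = np.sqrt(
        np.mean(np.sum((out[:, idx] - ref_fit) ** 2, axis=2), axis=1)
    )
    return SuperpositionResult(
        rotated_trajectory=traj.with_coordinates(out),
        per_frame_rmsd=per_frame,
        reference_frame=ref_frame,
    )


def iterative_mean_fit(
    traj: TrajectoryEnsemble,
    fit_selection: AtomSelection,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Superpose frames onto their converged mean structure.

    Alternates (fit all frames to the current mean over ``fit_selection``) and
    (recompute the mean) until the mean moves by less than ``tol`` Å RMSD.
    This is the standard essential-dynamics preprocessing step: it removes
    rigid-body translation/rotation so positional covariance reflects internal
    motion only. Non-convergence raises a warning and returns the best iterate.
    """
    idx = fit_selection.as_array()
    result = kabsch_superpose(traj, fit_selection, reference=0)
    mean = result.rotated_trajectory.coordinates[:, idx].mean(axis=0)
    converged = False
    iterations = 1
    for iterations in range(2, max_iter + 2):
        result = kabsch_superpose(traj, fit_selection, reference=mean)
        new_mean = result.rotated_trajectory.coordinates[:, idx].mean(axis=0)
        shift = rmsd(new_mean, mean)
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"iterative mean fit did not converge within {max_iter} iterations",
            stacklevel=2,
        )
    result.reference_frame = -1
    result.mean_structure = mean
    result.n_iterations = iterations
    result.converged = converged
    return result
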