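"""Geometric hydrogen-bond detection, occupancy tables, and water bridges.

Occupancy is the fraction of trajectory frames in which a donor–acceptor pair
satisfies a geometric criterion. The default criterion is a heavy-atom
donor–acceptor distance ≤ 3.5 Å (inclusive); when explicit hydrogens are
present and ``heavy_atom_only`` is off, a donor–H···acceptor angle cutoff is
applied in addition. Heavy-atom-only defaults suit Cα/heavy-atom ensembles
that carry no hydrogens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SelectionError, ValidationError
from .trajectory_core import Atom, AtomSelection, TrajectoryEnsemble

__all__ = [
    "HBondCriteria",
    "OccupancyTable",
    "detect_hbonds_frame",
    "occupancy",
    "occupancy_from_distances",
    "occupancy_table",
    "water_bridges",
    "resolve_atom_label",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})
_H_COVALENT_CUTOFF = 1.25  # Å, D–H bond detection


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    ``donor_acceptor_cutoff``: heavy-atom D–A distance in Å (inclusive bound).
    ``angle_cutoff``: minimum D–H···A angle in degrees, applied only when
    hydrogens exist and ``heavy_atom_only`` is False.
    """

    donor_acceptor_cutoff: float = 3.5
    angle_cutoff: float = 120.0
    heavy_atom_only: bool = True

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0:
            raise ValidationError("donor_acceptor_cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValidationError("angle_cutoff must be in (0, 180]")


@dataclass
class OccupancyTable:
    """Rows of (ligand_atom, protein_atom, occupancy), sorted descending."""

    rows: list[tuple[str, str, float]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["ligand_atom", "protein_atom", "occupancy"])
        df["occupancy_pct"] = (df["occupancy"] * 100).round(1)
        return df


def _is_hydrogen(atom: Atom) -> bool:
    if atom.element:
        return atom.element.upper() == "H"
    return atom.name[:1].upper() == "H" or (
        atom.name[:1].isdigit() and atom.name[1:2].upper() == "H"
    )


def _angle_satisfied(
    coords: np.ndarray,
    atoms: tuple[Atom, ...],
    donor: int,
    acceptor: int,
    hydrogens: np.ndarray,
    angle_cutoff: float,
) -> bool:
    """True if some hydrogen covalently bound to the donor makes a
    D–H···A angle ≥ cutoff (angle at the hydrogen)."""
    d = coords[donor]
    h_near = hydrogens[np.linalg.norm(coords[hydrogens] - d, axis=1) <= _H_COVALENT_CUTOFF]
    if h_near.size == 0:
        return True  # donor carries no explicit hydrogen: distance-only
    a = coords[acceptor]
    for h in h_near:
        hd = d - coords[h]
        ha = a - coords[h]
        denom = np.linalg.norm(hd) * np.linalg.norm(ha)
        if denom == 0:
            continue
        cos = np.clip(np.dot(hd, ha) / denom, -1.0, 1.0)
        if np.degrees(np.arccos(cos)) >= angle_cutoff:
            return True
    return False


def detect_hbonds_frame(
    coords: np.ndarray,
    atoms: tuple[Atom, ...],
    donors: AtomSelection,
    acceptors: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int]]:
    """All (donor, acceptor) index pairs satisfying the criterion in one frame.

    Pairs within the same residue are excluded. ``coords`` has shape
    ``(n_atoms, 3)``.
    """
    coords = np.asarray(coords, dtype=float)
    di = donors.as_array()
    ai = acceptors.as_array()
    if di.size == 0 or ai.size == 0:
        return []
    dist = cdist(coords[di], coords[ai])
    hydrogens = np.array([k for k, at in enumerate(atoms) if _is_hydrogen(at)], dtype=int)
    use_angle = not criteria.heavy_atom_only and hydrogens.size > 0
    pairs: list[tuple[int, int]] = []
    for p, d_idx in enumerate(di):
        for q, a_idx in enumerate(ai):
            if d_idx == a_idx:
                continue
            da, aa = atoms[d_idx], atoms[a_idx]
            if (da.chain_id, da.residue_number) == (aa.chain_id, aa.residue_number):
                continue
            if dist[p, q] > criteria.donor_acceptor_cutoff:
                continue
            if use_angle and not _angle_satisfied(
                coords, atoms, d_idx, a_idx, hydrogens, criteria.angle_cutoff
            ):
                continue
            pairs.append((int(d_idx), int(a_idx)))
    return pairs


_LABEL_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]{0,3}?)(\d+)?-(\S+)$")


def resolve_atom_label(traj: TrajectoryEnsemble, label: str) -> int:
    """Resolve a label like ``ASN33-OD1`` or ``LIG-N4`` to a unique atom index.

    Residue-name matching is case-insensitive; the residue number may be
    omitted for single-residue species such as ligands.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise SelectionError(f"cannot parse atom label {label!r} (expected RES###-ATOM)")
    resname, resnum, atname = m.group(1).upper(), m.group(2), m.group(3).upper()
    hits = [
        i
        for i, a in enumerate(traj.atoms)
        if a.residue_name.upper() == resname
        and a.name.upper() == atname
        and (resnum is None or a.residue_number == int(resnum))
    ]
    if len(hits) != 1:
        raise SelectionError(f"label {label!r} resolves to {len(hits)} atoms, need exactly 1")
    return hits[0]


def occupancy(
    traj: TrajectoryEnsemble,
    donor: str,
    acceptor: str,
    criteria: HBondCriteria = HBondCriteria(),
    skip_frames: int = 0,
) -> float:
    """Fraction of frames in which one donor–acceptor pair is hydrogen-bonded.

    ``donor``/``acceptor`` are atom labels (``ASN33-OD1``, ``LIG-N4``).
    ``skip_frames`` drops the first frames (equilibration window) from the
    denominator; the default analyzes every frame.
    """
    di = resolve_atom_label(traj, donor)
    ai = resolve_atom_label(traj, acceptor)
    coords = traj.coordinates[skip_frames:]
    if coords.shape[0] == 0:
        raise ValidationError("no frames left after skip_frames")
    dist = np.linalg.norm(coords[:, di, :] - coords[:, ai, :], axis=1)
    bonded = dist <= criteria.donor_acceptor_cutoff
    if not criteria.heavy_atom_only:
        hydrogens = np.array(
            [k for k, at in enumerate(traj.atoms) if _is_hydrogen(at)], dtype=int
        )
        if hydrogens.size:
            for f in np.flatnonzero(bonded):
                if not _angle_satisfied(
                    coords[f], traj.atoms, di, ai, hydrogens, criteria.angle_cutoff
                ):
                    bonded[f] = False
    return float(np.mean(bonded))


def occupancy_from_distances(
    values: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> float:
    """Occupancy of a precomputed donor–acceptor distance series (Å)."""
    values = np.asarray(values, dtype=float)
    return float(np.mean(values <= criteria.donor_acceptor_cutoff))


def occupancy_table(
    traj: TrajectoryEnsemble,
    ligand_selection: AtomSelection,
    protein_polar_selection: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
    min_occupancy: float = 0.05,
    skip_frames: int = 0,
) -> OccupancyTable:
    """Per-pair occupancies for all ligand × protein polar atom pairs.

    Rows with occupancy ≥ ``min_occupancy`` are returned sorted descending by
    occupancy (ties: by labels), with labels formatted ``LIG-ATOM`` /
    ``RES###-ATOM``.
    """
    li = ligand_selection.as_array()
    pi = protein_polar_selection.as_array()
    if li.size == 0 or pi.size == 0:
        warnings.warn("empty ligand or protein selection; occupancy table is empty", stacklevel=2)
        return OccupancyTable(rows=[])
    coords = traj.coordinates[skip_frames:]
    # (F, L, P) pairwise distances
    diff = coords[:, li, None, :] - coords[:, None, pi, :]
    dist = np.sqrt(np.sum(diff**2, axis=3))
    frac = np.mean(dist <= criteria.donor_acceptor_cutoff, axis=0)
    rows = []
    for p, lig_idx in enumerate(li):
        for q, prot_idx in enumerate(pi):
            la, pa = traj.atoms[lig_idx], traj.atoms[prot_idx]
            if (la.chain_id, la.residue_number) == (pa.chain_id, pa.residue_number):
                continue
            occ = float(frac[p, q])
            if occ >= min_occupancy:
                lig_label = f"{la.residue_name}-{la.name}"
                rows.append((lig_label, pa.label, occ))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return OccupancyTable(rows=rows)


def water_bridges(
    coords: np.ndarray,
    atoms: tuple[Atom, ...],
    group_x: AtomSelection,
    group_y: AtomSelection,
    waters: AtomSelection | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int, int]]:
    """Waters simultaneously hydrogen-bonded to both groups in one frame.

    A bridge is a water oxygen within the distance criterion of at least one
    atom of ``group_x`` and one of ``group_y``; one triple
    ``(x_atom, water_oxygen, y_atom)`` per qualifying water is returned using
    the closest partner on each side. ``waters`` defaults to the oxygen atoms
    of residues named HOH/WAT/SOL.
    """
    coords = np.asarray(coords, dtype=float)
    if waters is None:
        waters = AtomSelection(
            indices=tuple(
                i
                for i, a in enumerate(atoms)
                if a.residue_name.upper() in WATER_RESNAMES
                and (a.element.upper() == "O" or a.name.upper() in {"O", "OW", "OH2"})
            )
        )
    wi = waters.as_array()
    xi = group_x.as_array()
    yi = group_y.as_array()
    if wi.size == 0 or xi.size == 0 or yi.size == 0:
        return []
    dx = cdist(coords[wi], coords[xi])
    dy = cdist(coords[wi], coords[yi])
    cutoff = criteria.donor_acceptor_cutoff
    bridges: list[tuple[int, int, int]] = []
    for w in range(wi.size):
        if dx[w].min() <= cutoff and dy[w].min() <= cutoff:
            bridges.append(
                (int(xi[np.argmin(dx[w])]), int(wi[w]), int(yi[np.argmin(dy[w])]))
            )
    return bridges
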