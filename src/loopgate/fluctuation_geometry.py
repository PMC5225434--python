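"""Per-residue fluctuation profiles, distance time series, and pocket-state
classification from the loop-gap distance.

The pocket of interest is gated by two flexible loops; the Cα–Cα distance
between one residue of each loop (the "gap") summarizes whether the pocket is
closed, semi-closed or open. The classifier is a simple two-threshold rule on
that distance, fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SelectionError, ValidationError
from .trajectory_core import (
    BACKBONE_NAMES,
    AtomSelection,
    TrajectoryEnsemble,
    iterative_mean_fit,
    select_atoms,
)

__all__ = [
    "RMSFProfile",
    "DistanceSeries",
    "PocketState",
    "DEFAULT_POCKET_THRESHOLDS",
    "compute_rmsf",
    "distance_series",
    "classify_pocket_state",
    "loop_gap_series",
]

#: (closed_max, open_min) in Å: gap ≤ 6.5 → closed, gap ≥ 12.0 → open.
DEFAULT_POCKET_THRESHOLDS = (6.5, 12.0)


@dataclass
class RMSFProfile:
    """Root-mean-square fluctuation per residue (Å)."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    atom_rmsf: np.ndarray | None = None  # per selected atom, same order as selection


@dataclass
class DistanceSeries:
    """A labelled per-frame distance series in Å."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"distance series {self.label!r} contains non-finite values")


@dataclass(frozen=True)
class PocketState:
    """Pocket conformation assigned from one gap distance."""

    state: str  # "closed" | "semi-closed" | "open"
    gap_distance: float


def compute_rmsf(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    prefit: bool = True,
    aggregate: str = "backbone",
) -> RMSFProfile:
    """Per-residue RMSF: sqrt(⟨|r_i − ⟨r_i⟩|²⟩) over frames, aggregated by residue.

    ``aggregate`` controls residue-level aggregation of the per-atom values:
    ``"backbone"`` averages over backbone atoms (N, CA, C, O) present in the
    selection (residues with none fall back to all their selected atoms),
    ``"calpha"`` keeps CA only, ``"all"`` averages every selected atom.
    With ``prefit=True`` the trajectory is superposed onto its converged mean
    over ``selection`` first; pass ``prefit=False`` only for pre-fitted input.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF is undefined for a single frame")
    if aggregate not in {"backbone", "calpha", "all"}:
        raise ValidationError(f"unknown aggregate mode {aggregate!r}")
    if prefit:
        traj = iterative_mean_fit(traj, selection).rotated_trajectory
    idx = selection.as_array()
    coords = traj.coordinates[:, idx, :]
    mean = coords.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    # atoms whose coordinates never change have exactly zero fluctuation;
    # guard against summation roundoff in the mean
    static = (coords == coords[0]).all(axis=(0, 2))
    atom_rmsf[static] = 0.0

    atoms = [traj.atoms[i] for i in idx]
    residues: dict[tuple[str, int], list[int]] = {}
    for k, atom in enumerate(atoms):
        residues.setdefault((atom.chain_id, atom.residue_number), []).append(k)

    res_numbers, res_rmsf = [], []
    for (_, resnum), members in residues.items():
        if aggregate == "calpha":
            chosen = [k for k in members if atoms[k].name.upper() == "CA"]
        elif aggregate == "backbone":
            chosen = [k for k in members if atoms[k].name.upper() in BACKBONE_NAMES]
        else:
            chosen = members
        if not chosen:
            chosen = members
        res_numbers.append(resnum)
        res_rmsf.append(float(np.mean(atom_rmsf[chosen])))

    return RMSFProfile(
        residue_numbers=np.asarray(res_numbers, dtype=int),
        rmsf=np.asarray(res_rmsf, dtype=float),
        atom_rmsf=atom_rmsf,
    )


def _resolve_single(traj: TrajectoryEnsemble, sel: "AtomSelection | str", what: str) -> int:
    if isinstance(sel, str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_atoms(traj, sel)
    if len(sel) != 1:
        raise SelectionError(f"{what} must resolve to exactly 1 atom, got {len(sel)}")
    return sel.indices[0]


def distance_series(
    traj: TrajectoryEnsemble,
    atom_a: "AtomSelection | str",
    atom_b: "AtomSelection | str",
) -> DistanceSeries:
    """Euclidean distance between two single atoms, per frame.

    ``atom_a``/``atom_b`` are single-atom selections (objects or query
    strings). The label is built from atom metadata, e.g.
    ``TH2900-N4__ASN33-OD1``-style ``A__B``.
    """
    ia = _resolve_single(traj, atom_a, "atom_a")
    ib = _resolve_single(traj, atom_b, "atom_b")
    if ia == ib:
        warnings.warn("distance series of an atom with itself is constant 0", stacklevel=2)
    diff = traj.coordinates[:, ia, :] - traj.coordinates[:, ib, :]
    label = f"{traj.atoms[ia].label}__{traj.atoms[ib].label}"
    return DistanceSeries(label=label, values=np.sqrt(np.sum(diff**2, axis=1)))


def classify_pocket_state(
    gap: float,
    thresholds: tuple[float, float] = DEFAULT_POCKET_THRESHOLDS,
) -> PocketState:
    """Classify a loop-gap distance as closed / semi-closed / open.

    ``gap ≤ closed_max`` → closed; ``gap ≥ open_min`` → open; otherwise
    semi-closed. Total and monotone in ``gap`` by construction.
    """
    closed_max, open_min = thresholds
    if not closed_max < open_min:
        raise ValidationError(f"thresholds must satisfy closed_max < open_min, got {thresholds}")
    if not np.isfinite(gap):
        raise ValidationError(f"gap distance must be finite, got {gap}")
    if gap <= closed_max:
        state = "closed"
    elif gap >= open_min:
        state = "open"
    else:
        state = "semi-closed"
    return PocketState(state=state, gap_distance=float(gap))


def loop_gap_series(
    traj: TrajectoryEnsemble,
    residue_a: int,
    residue_b: int,
) -> DistanceSeries:
    """Cα–Cα distance between two residues, per frame."""
    for res in (residue_a, residue_b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_atoms(traj, f"resid {res} and name CA")
        if len(sel) == 0:
            raise SelectionError(f"residue {res} has no CA atom")
    return distance_series(
        traj,
        f"resid {residue_a} and name CA",
        f"resid {residue_b} and name CA",
    )
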