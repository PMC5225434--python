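"""Dynamic cross-correlation matrix (DCCM) of atomic displacement vectors.

For atoms i, j with displacement vectors Δr from their trajectory-mean
positions (after rigid-body fitting),

    S_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i · Δr_i⟩ ⟨Δr_j · Δr_j⟩)

so S_ij ∈ [−1, 1]: +1 fully correlated, −1 fully anti-correlated motion.
The dot product contracts the full 3-D vectors (isotropic contraction), not
per-component correlations. Atoms with zero fluctuation have no defined
correlation and are masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma

from .errors import SelectionError, ValidationError
from .trajectory_core import AtomSelection, TrajectoryEnsemble, iterative_mean_fit

__all__ = ["CrossCorrelationMatrix", "compute_dccm", "block_correlation_score"]


@dataclass
class CrossCorrelationMatrix:
    """N×N normalized displacement correlations over a selection.

    ``values`` is a masked array: rows/columns of zero-fluctuation atoms are
    masked. ``residue_numbers`` maps matrix rows to residue numbers so loop
    blocks can be addressed by residue range.
    """

    selection: AtomSelection
    values: ma.MaskedArray
    residue_numbers: np.ndarray


def compute_dccm(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    prefit: bool = True,
) -> CrossCorrelationMatrix:
    """Compute the DCCM over ``selection`` (typically all Cα atoms)."""
    if traj.n_frames < 2:
        raise ValidationError("DCCM needs at least 2 frames")
    if prefit:
        traj = iterative_mean_fit(traj, selection).rotated_trajectory
    idx = selection.as_array()
    sub = traj.coordinates[:, idx, :]
    disp = sub - sub.mean(axis=0)
    # ⟨Δr_i · Δr_j⟩: contract frame and Cartesian axes
    inner = np.einsum("fia,fja->ij", disp, disp) / traj.n_frames
    var = np.diag(inner).copy()
    # an atom is static when its coordinates never change; roundoff in the
    # mean can leave var ~ 1e-32 for such atoms
    static = (var <= 0.0) | (sub == sub[0]).all(axis=(0, 2))
    if static.all():
        warnings.warn("all selected atoms are static; DCCM fully masked", stacklevel=2)
    norm = np.sqrt(np.where(static, 1.0, var))
    values = inner / np.outer(norm, norm)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    mask = np.zeros_like(values, dtype=bool)
    mask[static, :] = True
    mask[:, static] = True
    residue_numbers = np.asarray([traj.atoms[i].residue_number for i in idx], dtype=int)
    return CrossCorrelationMatrix(
        selection=selection,
        values=ma.MaskedArray(values, mask=mask),
        residue_numbers=residue_numbers,
    )


def block_correlation_score(
    matrix: CrossCorrelationMatrix,
    residues_a: tuple[int, int],
    residues_b: tuple[int, int],
) -> float:
    """Mean S_ij over the cross block of two residue ranges (inclusive).

    Negative scores mean the two regions move in an anti-correlated fashion;
    this is the summary statistic for loop–loop coupling.
    """
    lo_a, hi_a = residues_a
    lo_b, hi_b = residues_b
    in_a = (matrix.residue_numbers >= lo_a) & (matrix.residue_numbers <= hi_a)
    in_b = (matrix.residue_numbers >= lo_b) & (matrix.residue_numbers <= hi_b)
    if not in_a.any() or not in_b.any():
        raise SelectionError(
            f"residue ranges {residues_a} x {residues_b} select an empty block"
        )
    block = matrix.values[np.ix_(in_a, in_b)]
    score = block.mean()
    if score is ma.masked:
        raise ValidationError("block is fully masked (static atoms)")
    return float(score)
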