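"""Essential dynamics: positional covariance PCA, projections, and the
probability-based free-energy landscape with basin detection.

The covariance analysis follows the standard essential-dynamics recipe: after
rigid-body fitting, the 3N×3N positional covariance matrix

    C[3i+a, 3j+b] = ⟨(x_{i,a} − ⟨x_{i,a}⟩)(x_{j,b} − ⟨x_{j,b}⟩)⟩

is built over the trajectory (⟨·⟩ is the average over frames, divisor = frame
count) and diagonalized. Eigenvectors are the collective motion directions;
eigenvalues their mean-square amplitude in Å². Frames projected onto the top
two eigenvectors (PC1, PC2) span the collective-variable plane on which the
free-energy landscape ΔG(PC1, PC2) = −kB·T·ln[P/P_ref] is constructed by
Boltzmann inversion of the binned probability density, with the most populated
bin as the zero-energy reference so every basin has ΔG ≥ 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.ma as ma
from scipy import ndimage

from .errors import ValidationError
from .trajectory_core import (
    AtomSelection,
    TrajectoryEnsemble,
    iterative_mean_fit,
)

__all__ = [
    "BOLTZMANN_KCAL",
    "CovarianceModel",
    "ProjectionSeries",
    "FreeEnergySurface",
    "Basin",
    "ModeMotion",
    "build_covariance",
    "diagonalize",
    "project",
    "extreme_frame",
    "build_landscape",
    "count_basins",
    "mode_motion",
]

#: Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041


@dataclass
class CovarianceModel:
    """Mean structure, 3N×3N positional covariance, and its eigenpairs.

    ``eigenvectors`` are stored as rows (``eigenvectors[k]`` is the k-th mode,
    a unit 3N-vector), sorted by descending eigenvalue, each flipped so its
    largest-magnitude component is positive.
    """

    selection: AtomSelection
    mean: np.ndarray  # (N, 3) Å
    matrix_c: np.ndarray  # (3N, 3N) Å²
    eigenvalues: np.ndarray | None = None  # (3N,) Å², descending
    eigenvectors: np.ndarray | None = None  # (3N, 3N), rows are modes

    @property
    def n_atoms(self) -> int:
        return len(self.selection)


@dataclass
class ProjectionSeries:
    """Per-frame projections onto two covariance eigenvectors (Å)."""

    pc1: np.ndarray
    pc2: np.ndarray
    mode_indices: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.pc2 = np.asarray(self.pc2, dtype=float)
        if self.pc1.shape != self.pc2.shape or self.pc1.ndim != 1:
            raise ValidationError("pc1 and pc2 must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return self.pc1.size


@dataclass(frozen=True)
class Basin:
    """A local free-energy minimum on the landscape grid."""

    center: tuple[float, float]  # (pc1, pc2) bin centers, Å
    delta_g: float  # kcal/mol above the global minimum
    bin_index: tuple[int, int]


@dataclass
class FreeEnergySurface:
    """2-D binned ΔG grid over (PC1, PC2), zeroed at the most populated bin.

    ``delta_g`` is a masked array (masked where ``counts == 0``); unmasked
    values satisfy ``delta_g.min() == 0`` and ``delta_g >= 0``.
    """

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    counts: np.ndarray
    delta_g: ma.MaskedArray
    temperature: float
    kB: float = BOLTZMANN_KCAL
    basins: list[Basin] = field(default_factory=list)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.pc1_edges[:-1] + self.pc1_edges[1:]),
            0.5 * (self.pc2_edges[:-1] + self.pc2_edges[1:]),
        )


@dataclass
class ModeMotion:
    """Per-atom displacement vectors of one collective mode (porcupine data)."""

    mode: int
    amplitude: float
    displacements: np.ndarray  # (N, 3) Å


def build_covariance(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    prefit: bool = True,
) -> CovarianceModel:
    """Build (and diagonalize) the positional covariance matrix.

    With ``prefit=True`` the trajectory is first superposed onto its converged
    mean over ``selection`` (see :func:`~loopgate.trajectory_core.iterative_mean_fit`),
    the standard way to keep rigid-body motion out of the covariance.
    The divisor is the frame count (population convention).
    """
    if traj.n_frames < 2:
        raise ValidationError("covariance needs at least 2 frames")
    if prefit:
        traj = iterative_mean_fit(traj, selection).rotated_trajectory
    idx = selection.as_array()
    x = traj.coordinates[:, idx, :].reshape(traj.n_frames, -1)  # (F, 3N)
    mean_flat = x.mean(axis=0)
    xc = x - mean_flat
    c = (xc.T @ xc) / traj.n_frames
    c = 0.5 * (c + c.T)  # enforce exact symmetry against roundoff
    model = CovarianceModel(
        selection=selection,
        mean=mean_flat.reshape(-1, 3),
        matrix_c=c,
    )
    return diagonalize(model)


def diagonalize(model: CovarianceModel, symmetry_tol: float = 1e-8) -> CovarianceModel:
    """Fill the eigenpairs of a covariance model (descending eigenvalues).

    Eigenvalues are clipped at zero (the matrix is PSD up to roundoff); each
    eigenvector's sign is fixed so its largest-magnitude component is
    positive, making projections reproducible across platforms.
    """
    c = model.matrix_c
    asym = np.max(np.abs(c - c.T)) if c.size else 0.0
    if asym > symmetry_tol:
        raise ValidationError(f"covariance matrix asymmetric beyond tolerance ({asym:g})")
    evals, evecs = np.linalg.eigh(0.5 * (c + c.T))
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    for k in range(evecs.shape[0]):
        j = np.argmax(np.abs(evecs[k]))
        if evecs[k, j] < 0:
            evecs[k] = -evecs[k]
    model.eigenvalues = evals
    model.eigenvectors = evecs
    return model


def project(
    traj: TrajectoryEnsemble,
    model: CovarianceModel,
    modes: tuple[int, int] = (1, 2),
) -> ProjectionSeries:
    """Project frames onto two covariance eigenvectors (1-based mode indices)."""
    if model.eigenvectors is None:
        raise ValidationError("model has no eigenpairs; call diagonalize first")
    idx = model.selection.as_array()
    if idx.max(initial=-1) >= traj.n_atoms:
        raise ValidationError("model selection out of range for this trajectory")
    x = traj.coordinates[:, idx, :].reshape(traj.n_frames, -1)
    xc = x - model.mean.reshape(-1)
    k1, k2 = modes
    n_modes = model.eigenvectors.shape[0]
    if not (1 <= k1 <= n_modes and 1 <= k2 <= n_modes):
        raise ValidationError(f"mode indices {modes} out of range (1..{n_modes})")
    return ProjectionSeries(
        pc1=xc @ model.eigenvectors[k1 - 1],
        pc2=xc @ model.eigenvectors[k2 - 1],
        mode_indices=(k1, k2),
    )


def extreme_frame(proj: ProjectionSeries, mode: int = 1, side: str = "max") -> int:
    """Index of the frame with the extreme projection on one mode.

    Ties resolve to the earliest frame. ``mode`` refers to positions in the
    series (1 → ``pc1``, 2 → ``pc2``), ``side`` is ``"max"`` or ``"min"``.
    """
    if proj.n_frames == 0:
        raise ValidationError("empty projection series")
    if mode == 1:
        values = proj.pc1
    elif mode == 2:
        values = proj.pc2
    else:
        raise ValidationError(f"mode must be 1 or 2, got {mode}")
    if side == "max":
        return int(np.argmax(values))
    if side == "min":
        return int(np.argmin(values))
    raise ValidationError(f"side must be 'max' or 'min', got {side!r}")


def build_landscape(
    proj: ProjectionSeries,
    temperature: float = 300.0,
    n_bins: int = 50,
    padding: float = 0.01,
) -> FreeEnergySurface:
    """Boltzmann-invert the binned (PC1, PC2) density into a ΔG surface.

    ΔG(bin) = −kB·T·[ln P(bin) − ln P_max], where P is the fraction of frames
    in the bin and P_max the fraction in the most populated bin, so the global
    minimum is exactly 0 and empty bins are masked. The grid spans the
    observed projection ranges with fractional ``padding`` on each side.
    """
    if temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    if proj.n_frames < n_bins:
        warnings.warn(
            f"only {proj.n_frames} samples for {n_bins}x{n_bins} bins; "
            "landscape will be noisy",
            stacklevel=2,
        )

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = padding * span if span > 0 else max(abs(lo), 1.0) * 1e-6 + 1e-12
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    e1, e2 = _edges(proj.pc1), _edges(proj.pc2)
    counts, _, _ = np.histogram2d(proj.pc1, proj.pc2, bins=(e1, e2))
    counts = counts.astype(int)
    total = counts.sum()
    mask = counts == 0
    with np.errstate(divide="ignore"):
        log_p = np.log(counts / total, where=~mask, out=np.full(counts.shape, -np.inf))
    delta_g = -BOLTZMANN_KCAL * temperature * (log_p - log_p.max()) + 0.0  # kill -0.0
    return FreeEnergySurface(
        pc1_edges=e1,
        pc2_edges=e2,
        counts=counts,
        delta_g=ma.MaskedArray(delta_g, mask=mask),
        temperature=temperature,
    )


def count_basins(
    surface: FreeEnergySurface,
    depth_cutoff: float = 2.0,
    min_separation_bins: int = 3,
    min_barrier: float = 0.5,
    smoothing_sigma: float = 1.0,
) -> list[Basin]:
    """Detect free-energy basins on the ΔG grid by topological persistence.

    Bins are flooded in order of increasing ΔG (8-connected); when two
    growing catchments meet, the shallower one survives as a distinct basin
    only if the saddle between them lies at least ``min_barrier`` kcal/mol
    above its own minimum — otherwise it is a counting-noise wrinkle of the
    deeper basin and is merged into it. Catchments separated by empty
    (masked) bins never meet and always stay distinct.

    Detection runs on a ΔG grid recomputed from Gaussian-smoothed counts
    (``smoothing_sigma`` in bins; 0 disables smoothing) to suppress local
    minima created by Poisson counting noise; the *reported* ΔG of each basin
    is read off the raw (unsmoothed) grid, as the minimum over the detected
    bin's 3×3 neighbourhood.

    Surviving minima are then filtered to ΔG ≤ ``depth_cutoff`` kcal/mol
    above the global minimum, and minima closer than ``min_separation_bins``
    (Chebyshev distance) are merged keeping the deeper one. The result is
    sorted by (ΔG, row, col) and also stored on ``surface.basins``.
    """
    raw_dg = surface.delta_g.filled(np.inf)
    if smoothing_sigma > 0:
        smooth = ndimage.gaussian_filter(
            surface.counts.astype(float), smoothing_sigma, mode="nearest"
        )
        with np.errstate(divide="ignore"):
            log_p = np.where(smooth > 0, np.log(np.maximum(smooth, 1e-300)), -np.inf)
        dg = -surface.kB * surface.temperature * (log_p - log_p.max()) + 0.0
        dg[surface.counts == 0] = np.inf  # keep the raw mask
    else:
        dg = raw_dg
    nrow, ncol = dg.shape
    finite = np.isfinite(dg)
    cells = np.argwhere(finite)
    order = cells[np.lexsort((cells[:, 1], cells[:, 0], dg[finite]))]

    # union-find over grid cells; each component root tracks its minimum
    comp = -np.ones(dg.shape, dtype=int)  # component id per processed cell
    parent: list[int] = []
    comp_min: list[tuple[float, int, int]] = []  # (ΔG, row, col) of the minimum
    confirmed: list[int] = []

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for r, c in order:
        g = dg[r, c]
        roots = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < nrow and 0 <= cc < ncol and comp[rr, cc] >= 0:
                    root = find(comp[rr, cc])
                    if root not in roots:
                        roots.append(root)
        if not roots:
            comp[r, c] = len(parent)
            parent.append(len(parent))
            comp_min.append((float(g), int(r), int(c)))
            continue
        roots.sort(key=lambda i: comp_min[i])
        deepest = roots[0]
        comp[r, c] = deepest
        for other in roots[1:]:
            # this cell is the saddle where `other`'s catchment dies
            if g - comp_min[other][0] >= min_barrier:
                confirmed.append(other)
            parent[other] = deepest

    # the deepest minimum of each surviving component never dies
    confirmed.extend({find(i) for i in range(len(parent))})

    def raw_depth(r: int, c: int) -> float:
        window = raw_dg[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        return float(window.min())

    candidates = sorted(
        (raw_depth(r, c), r, c) for _, r, c in (comp_min[i] for i in set(confirmed))
    )

    kept: list[tuple[float, int, int]] = []
    for g, r, c in candidates:
        if not np.isfinite(g) or g > depth_cutoff:
            continue
        if any(max(abs(r - r0), abs(c - c0)) < min_separation_bins for _, r0, c0 in kept):
            continue
        kept.append((g, r, c))
    c1, c2 = surface.bin_centers()
    basins = [
        Basin(center=(float(c1[r]), float(c2[c])), delta_g=g, bin_index=(r, c))
        for g, r, c in kept
    ]
    surface.basins = basins
    return basins


def mode_motion(model: CovarianceModel, mode: int, amplitude: float) -> ModeMotion:
    """Per-atom displacement vectors of one mode scaled by ``amplitude`` (Å).

    The output is the porcupine-plot payload: one 3-vector per selected atom,
    ``amplitude × eigenvector`` reshaped to (N, 3).
    """
    if model.eigenvectors is None:
        raise ValidationError("model has no eigenpairs; call diagonalize first")
    n_modes = model.eigenvectors.shape[0]
    if not 1 <= mode <= n_modes:
        raise ValidationError(f"mode {mode} out of range (1..{n_modes})")
    disp = amplitude * model.eigenvectors[mode - 1].reshape(-1, 3)
    return ModeMotion(mode=mode, amplitude=amplitude, displacements=disp)
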