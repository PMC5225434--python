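"""Synthetic conformational ensembles with planted, analytically known
statistics.

Every generator here is a pure function of its spec and seed and emulates one
statistical feature of a real MD trajectory ensemble:

* :func:`generate_gaussian_ensemble` — frames drawn about a mean structure
  along orthonormal collective modes with chosen amplitudes, so the population
  covariance is exactly Σ amplitude²·mode·modeᵀ + σ²·I.
* :func:`generate_two_loop_gating_ensemble` — a Cα chain whose two pocket
  loops move along a planted gating mode (approaching / opening /
  anti-parallel), driving DCCM blocks, RMSF contrast, and a bimodal loop-gap
  distance.
* :func:`generate_basin_projection_ensemble` — (PC1, PC2) samples from a
  Gaussian mixture whose basin free-energy offsets are −kB·T·ln(w_i/w_max) in
  closed form.
* :func:`generate_hbond_distance_series` — a two-state Markov donor–acceptor
  distance series whose stationary bound fraction is the target occupancy.

These generators emulate statistics, not dynamics: no force field, no
integrator, no solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .essential_dynamics import BOLTZMANN_KCAL, ProjectionSeries
from .fluctuation_geometry import DistanceSeries
from .trajectory_core import Atom, TrajectoryEnsemble

__all__ = [
    "GaussianEnsembleSpec",
    "BasinSpec",
    "HBondSeriesSpec",
    "make_calpha_topology",
    "helical_mean_structure",
    "generate_gaussian_ensemble",
    "gating_displacement_pattern",
    "generate_two_loop_gating_ensemble",
    "generate_basin_projection_ensemble",
    "generate_hbond_distance_series",
    "hbond_pair_ensemble",
]


def helical_mean_structure(n_residues: int) -> np.ndarray:
    """An idealized α-helical Cα trace: (n, 3) coordinates in Å.

    100° turn and 1.5 Å rise per residue at 2.3 Å radius — a convenient
    non-degenerate mean structure for Gaussian ensembles (rigid-body fitting
    onto a point cloud with spatial extent is well conditioned, unlike a
    collapsed all-zero mean).
    """
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack((2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i))


def make_calpha_topology(
    n_residues: int,
    residue_name: str = "ALA",
    chain_id: str = "A",
) -> tuple[Atom, ...]:
    """A minimal Cα-only topology of ``n_residues`` residues numbered from 1."""
    return tuple(
        Atom(
            serial=i + 1,
            name="CA",
            residue_name=residue_name,
            residue_number=i + 1,
            chain_id=chain_id,
            element="C",
        )
        for i in range(n_residues)
    )


# ---------------------------------------------------------------------------
# Gaussian mode ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Frames = mean + Σ_k amplitude_k·z_k·mode_k + isotropic noise.

    ``mode_vectors`` must be mutually orthonormal unit 3N-vectors;
    ``mode_amplitudes`` (Å, the standard deviations along each mode) must be
    positive and strictly decreasing.
    """

    mean_structure: np.ndarray  # (n_atoms, 3) Å
    mode_vectors: list[np.ndarray] = field(default_factory=list)
    mode_amplitudes: list[float] = field(default_factory=list)
    isotropic_noise_sigma: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def validate(self) -> None:
        mean = np.asarray(self.mean_structure, dtype=float)
        if mean.ndim != 2 or mean.shape[1] != 3:
            raise SpecError(f"mean_structure must be (n_atoms, 3), got {mean.shape}")
        if self.n_frames < 2:
            raise SpecError("n_frames must be at least 2")
        if self.isotropic_noise_sigma < 0:
            raise SpecError("isotropic_noise_sigma must be non-negative")
        if len(self.mode_vectors) != len(self.mode_amplitudes):
            raise SpecError("mode_vectors and mode_amplitudes lengths differ")
        dim = mean.size
        amps = list(self.mode_amplitudes)
        if any(a <= 0 for a in amps):
            raise SpecError("mode amplitudes must be positive")
        if any(b >= a for a, b in zip(amps, amps[1:])):
            raise SpecError("mode amplitudes must be strictly decreasing")
        if self.mode_vectors:
            m = np.stack([np.asarray(v, dtype=float).reshape(-1) for v in self.mode_vectors])
            if m.shape[1] != dim:
                raise SpecError(f"mode vectors must have length {dim}, got {m.shape[1]}")
            gram = m @ m.T
            if not np.allclose(gram, np.eye(m.shape[0]), atol=1e-8):
                raise SpecError("mode vectors must be mutually orthonormal")


def generate_gaussian_ensemble(spec: GaussianEnsembleSpec) -> TrajectoryEnsemble:
    """Draw frames with the exact planted covariance structure of ``spec``."""
    spec.validate()
    mean = np.asarray(spec.mean_structure, dtype=float)
    n_atoms = mean.shape[0]
    rng = np.random.default_rng(spec.seed)
    flat = np.tile(mean.reshape(1, -1), (spec.n_frames, 1))
    if spec.mode_vectors:
        modes = np.stack(
            [np.asarray(v, dtype=float).reshape(-1) for v in spec.mode_vectors]
        )
        z = rng.standard_normal((spec.n_frames, modes.shape[0]))
        flat += (z * np.asarray(spec.mode_amplitudes)) @ modes
    if spec.isotropic_noise_sigma > 0:
        flat += spec.isotropic_noise_sigma * rng.standard_normal(flat.shape)
    return TrajectoryEnsemble(
        atoms=make_calpha_topology(n_atoms),
        coordinates=flat.reshape(spec.n_frames, n_atoms, 3),
    )


# ---------------------------------------------------------------------------
# Two-loop gating ensembles
# ---------------------------------------------------------------------------

GATING_MODES = ("anti-parallel", "approaching", "opening")


def _gating_mean_structure(
    n_residues: int,
    loop1: tuple[int, int],
    loop2: tuple[int, int],
    initial_gap: float,
) -> np.ndarray:
    """Mean Cα geometry: the two loops face each other across the pocket.

    Loop residues sit on short strands at x = ∓gap/2 (pocket center at the
    origin), aligned so the residues at matching offsets from each loop's
    midpoint are exactly ``initial_gap`` apart along x. Remaining residues sit
    on a non-intersecting helix behind the pocket — their placement carries no
    signal, only the isotropic noise does.
    """
    coords = np.empty((n_residues, 3))
    spacing = 3.8  # Å, typical Cα-Cα distance
    for i in range(n_residues):
        theta = 2.0 * np.pi * i / max(n_residues, 1)
        coords[i] = (14.0 * np.cos(theta), 14.0 * np.sin(theta), -30.0 + 0.25 * i)
    mid1 = 0.5 * (loop1[0] + loop1[1])
    mid2 = 0.5 * (loop2[0] + loop2[1])
    for res in range(loop1[0], loop1[1] + 1):
        coords[res - 1] = (-initial_gap / 2.0, spacing * (res - mid1), 0.0)
    for res in range(loop2[0], loop2[1] + 1):
        coords[res - 1] = (+initial_gap / 2.0, spacing * (res - mid2), 0.0)
    return coords


def gating_displacement_pattern(
    n_residues: int,
    loop1: tuple[int, int],
    loop2: tuple[int, int],
    mode: str,
) -> np.ndarray:
    """Planted displacement pattern (n_residues, 3), in units of the gating
    coordinate: each loop-1 atom moves along ``u1``, each loop-2 atom along
    ``u2``, everything else stays.

    With the pocket center at the origin and loop 1 at −x, loop 2 at +x:
    ``approaching`` → both loops move toward the center; ``opening`` → both
    move apart; ``anti-parallel`` → both move in the same global direction
    (loop 1 toward the center, loop 2 away).
    """
    if mode not in GATING_MODES:
        raise SpecError(f"mode must be one of {GATING_MODES}, got {mode!r}")
    u1 = np.array([1.0, 0.0, 0.0])  # loop 1 toward pocket center (+x)
    if mode == "approaching":
        u2 = np.array([-1.0, 0.0, 0.0])
    elif mode == "opening":
        u1 = -u1
        u2 = np.array([1.0, 0.0, 0.0])
    else:  # anti-parallel: same global direction
        u2 = np.array([1.0, 0.0, 0.0])
    pattern = np.zeros((n_residues, 3))
    for res in range(loop1[0], loop1[1] + 1):
        pattern[res - 1] = u1
    for res in range(loop2[0], loop2[1] + 1):
        pattern[res - 1] = u2
    return pattern


def generate_two_loop_gating_ensemble(
    n_residues: int = 155,
    loop1: tuple[int, int] = (23, 29),
    loop2: tuple[int, int] = (139, 143),
    mode: str = "approaching",
    amplitude: float = 2.5,
    n_frames: int = 5000,
    seed: int = 0,
    noise_sigma: float = 0.3,
    initial_gap: float = 11.0,
    state_probability: float = 0.35,
    state_spread: float = 0.15,
) -> TrajectoryEnsemble:
    """Cα ensemble whose dominant covariance mode gates the two pocket loops.

    The gating coordinate is two-state: with probability ``state_probability``
    a frame is in the displaced state (coordinate ≈ 1), otherwise in the rest
    state (≈ 0), plus Gaussian spread ``state_spread``; loop atoms move by
    ``amplitude × coordinate`` along the planted pattern of
    :func:`gating_displacement_pattern`, all atoms carry isotropic noise
    ``noise_sigma``. ``amplitude=0`` yields a purely isotropic ensemble.

    The two-state coordinate makes the loop-gap distribution bimodal
    (toward smaller gaps for ``approaching``, larger for ``opening``) while
    the anti-/parallel loop displacements set the sign of the loop–loop
    cross-correlation block.
    """
    if not (1 <= loop1[0] <= loop1[1] <= n_residues):
        raise SpecError(f"loop1 range {loop1} outside chain 1..{n_residues}")
    if not (1 <= loop2[0] <= loop2[1] <= n_residues):
        raise SpecError(f"loop2 range {loop2} outside chain 1..{n_residues}")
    if not (loop1[1] < loop2[0] or loop2[1] < loop1[0]):
        raise SpecError(f"loop ranges {loop1} and {loop2} overlap")
    if amplitude < 0 or noise_sigma < 0:
        raise SpecError("amplitude and noise_sigma must be non-negative")
    if not 0 <= state_probability <= 1:
        raise SpecError("state_probability must be in [0, 1]")

    mean = _gating_mean_structure(n_residues, loop1, loop2, initial_gap)
    pattern = gating_displacement_pattern(n_residues, loop1, loop2, mode)
    rng = np.random.default_rng(seed)
    state = rng.random(n_frames) < state_probability
    z = state + state_spread * rng.standard_normal(n_frames)
    coords = (
        mean[None, :, :]
        + amplitude * z[:, None, None] * pattern[None, :, :]
        + noise_sigma * rng.standard_normal((n_frames, n_residues, 3))
    )
    return TrajectoryEnsemble(atoms=make_calpha_topology(n_residues), coordinates=coords)


# ---------------------------------------------------------------------------
# Basin projection ensembles
# ---------------------------------------------------------------------------

@dataclass
class BasinSpec:
    """Gaussian mixture over the (PC1, PC2) plane.

    Each basin is an isotropic 2-D Gaussian with weight ``weights[i]`` and
    standard deviation ``widths[i]``; the analytic free-energy offset of basin
    i relative to the most populated one is −kB·T·ln(w_i/w_max).
    """

    centers: list[tuple[float, float]]
    weights: list[float]
    widths: list[float]
    temperature: float = 300.0

    def validate(self) -> None:
        k = len(self.centers)
        if k == 0:
            raise SpecError("at least one basin required")
        if len(self.weights) != k or len(self.widths) != k:
            raise SpecError("centers, weights and widths must have equal length")
        if any(w <= 0 for w in self.weights):
            raise SpecError("weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise SpecError(f"weights must sum to 1, got {sum(self.weights)!r}")
        if any(s <= 0 for s in self.widths):
            raise SpecError("widths must be positive")
        if self.temperature <= 0:
            raise SpecError("temperature must be positive")

    def true_delta_g(self) -> np.ndarray:
        """Analytic ΔG of each basin center relative to the heaviest basin,
        kcal/mol (equal widths assumed for the probability-density reading)."""
        w = np.asarray(self.weights, dtype=float)
        return -BOLTZMANN_KCAL * self.temperature * np.log(w / w.max())


def generate_basin_projection_ensemble(
    spec: BasinSpec,
    n_frames: int,
    seed: int = 0,
) -> ProjectionSeries:
    """Sample (PC1, PC2) points from the basin mixture of ``spec``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(spec.centers), size=n_frames, p=spec.weights)
    centers = np.asarray(spec.centers, dtype=float)
    widths = np.asarray(spec.widths, dtype=float)
    pts = centers[which] + widths[which, None] * rng.standard_normal((n_frames, 2))
    return ProjectionSeries(pc1=pts[:, 0], pc2=pts[:, 1])


# ---------------------------------------------------------------------------
# Hydrogen-bond distance series
# ---------------------------------------------------------------------------

@dataclass
class HBondSeriesSpec:
    """Two-state (bound/unbound) donor–acceptor distance series.

    The state sequence is a stationary first-order Markov chain whose bound
    fraction is ``target_occupancy`` and whose mean bound dwell time is
    ``mean_dwell_frames``. Bound-state distances are drawn about
    ``bound_distance_mean`` (below ``criterion_cutoff``), unbound about
    ``unbound_distance_mean`` (above it); draws are clipped to the correct
    side of the cutoff so the realized state fraction and the measured
    occupancy coincide.
    """

    target_occupancy: float = 0.5
    bound_distance_mean: float = 3.0
    unbound_distance_mean: float = 5.5
    distance_sigma: float = 0.15
    criterion_cutoff: float = 3.5
    mean_dwell_frames: float = 10.0
    angle_behavior: bool = True  # angle criterion satisfied whenever bound
    n_frames: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise SpecError(f"target_occupancy must be in [0, 1], got {self.target_occupancy}")
        if not self.bound_distance_mean < self.criterion_cutoff < self.unbound_distance_mean:
            raise SpecError(
                "need bound_distance_mean < criterion_cutoff < unbound_distance_mean, "
                f"got {self.bound_distance_mean} / {self.criterion_cutoff} / "
                f"{self.unbound_distance_mean}"
            )
        if self.distance_sigma < 0:
            raise SpecError("distance_sigma must be non-negative")
        if self.mean_dwell_frames < 1:
            raise SpecError("mean_dwell_frames must be >= 1")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")


def _markov_states(spec: HBondSeriesSpec, rng: np.random.Generator) -> np.ndarray:
    occ = spec.target_occupancy
    n = spec.n_frames
    if occ == 0.0:
        return np.zeros(n, dtype=bool)
    if occ == 1.0:
        return np.ones(n, dtype=bool)
    p_leave_bound = 1.0 / spec.mean_dwell_frames
    p_enter_bound = min(1.0, occ / (1.0 - occ) * p_leave_bound)
    # recompute leave rate if the enter rate saturated, to keep stationarity
    if p_enter_bound == 1.0:
        p_leave_bound = (1.0 - occ) / occ
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < occ  # start from the stationary distribution
    u = rng.random(n - 1)
    for t in range(1, n):
        if states[t - 1]:
            states[t] = u[t - 1] >= p_leave_bound
        else:
            states[t] = u[t - 1] < p_enter_bound
    return states


def generate_hbond_distance_series(spec: HBondSeriesSpec) -> DistanceSeries:
    """Distance series whose fraction below the cutoff equals the planted
    occupancy up to Markov-chain sampling noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bound = _markov_states(spec, rng)
    noise = spec.distance_sigma * rng.standard_normal(spec.n_frames)
    values = np.where(
        bound,
        np.clip(spec.bound_distance_mean + noise, 0.5, spec.criterion_cutoff - 1e-3),
        np.maximum(spec.unbound_distance_mean + noise, spec.criterion_cutoff + 1e-3),
    )
    return DistanceSeries(label="synthetic-donor__synthetic-acceptor", values=values)


def hbond_pair_ensemble(
    spec: HBondSeriesSpec,
    ligand: tuple[str, str] = ("LIG", "N4"),
    protein: tuple[str, int, str] = ("ASN", 33, "OD1"),
) -> TrajectoryEnsemble:
    """Two-atom ensemble realizing a planted donor–acceptor distance series.

    The ligand atom sits at the origin; the protein atom at (d_t, 0, 0) per
    frame, so :func:`loopgate.hbond.occupancy` on the pair measures the
    planted occupancy directly.
    """
    series = generate_hbond_distance_series(spec)
    lig_resname, lig_atom = ligand
    prot_resname, prot_resnum, prot_atom = protein
    atoms = (
        Atom(serial=1, name=lig_atom, residue_name=lig_resname, residue_number=900,
             chain_id="A", element="N"),
        Atom(serial=2, name=prot_atom, residue_name=prot_resname,
             residue_number=prot_resnum, chain_id="A", element="O"),
    )
    n = series.values.size
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = series.values
    return TrajectoryEnsemble(atoms=atoms, coordinates=coords)
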