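"""Full-workflow orchestration: fit → RMSF → PCA → FEL → DCCM → H-bond → gap.

One :class:`AnalysisConfig` describes a set of labelled input ensembles (the
apo / ligand-bound systems of a comparative study) plus every analysis
parameter; :func:`run_pipeline` runs each stage on each ensemble, writes tidy
CSV outputs, and assembles a cross-ensemble comparison table (basin counts,
loop–loop correlation block scores, modal pocket state). Stage failures are
logged and do not stop independent stages.
"""

from __future__ import annotations

import json
import logging
import platform
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import block_correlation_score, compute_dccm
from .errors import ConfigError, LoopgateError
from .essential_dynamics import (
    build_covariance,
    build_landscape,
    count_basins,
    extreme_frame,
    project,
)
from .fluctuation_geometry import (
    DEFAULT_POCKET_THRESHOLDS,
    classify_pocket_state,
    compute_rmsf,
    loop_gap_series,
)
from .hbond import HBondCriteria, occupancy_table
from .synthetic_data import (
    GaussianEnsembleSpec,
    HBondSeriesSpec,
    generate_gaussian_ensemble,
    generate_two_loop_gating_ensemble,
    hbond_pair_ensemble,
    make_calpha_topology,
)
from .trajectory_core import (
    TrajectoryEnsemble,
    iterative_mean_fit,
    read_multimodel_pdb,
    read_xyz_trajectory,
    select_atoms,
    write_xyz_trajectory,
)

__all__ = ["EnsembleInput", "AnalysisConfig", "PipelineReport", "run_pipeline",
           "load_config", "simulate_from_spec"]

logger = logging.getLogger("loopgate.pipeline")


@dataclass
class EnsembleInput:
    """One labelled input trajectory."""

    label: str
    path: str
    format: str = "xyz"  # "xyz" | "pdb"
    n_residues: int | None = None  # Cα topology size for XYZ input


@dataclass
class AnalysisConfig:
    """Every knob of the comparative pipeline, with the package defaults."""

    ensembles: list[EnsembleInput] = field(default_factory=list)
    fit_selection: str = "name CA"
    analysis_selection: str = "name CA"
    loop1: tuple[int, int] = (23, 29)
    loop2: tuple[int, int] = (139, 143)
    gap_residues: tuple[int, int] = (27, 142)
    fel_bins: int = 50
    temperature: float = 300.0
    basin_depth_cutoff: float = 2.0
    basin_min_separation: int = 3
    hbond_cutoff: float = 3.5
    hbond_min_occupancy: float = 0.05
    hbond_skip_frames: int = 0
    ligand_selection: str = "hetero"
    protein_polar_selection: str = "protein and name O,N,OD1,OD2,ND2,NE1,NZ,OH,OE1,OE2,NE2,OG,OG1,SG"
    pocket_thresholds: tuple[float, float] = DEFAULT_POCKET_THRESHOLDS
    output_dir: str = "loopgate_out"
    seed: int = 0

    def validate(self) -> None:
        labels = [e.label for e in self.ensembles]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"ensemble labels must be unique, got {labels}")
        for e in self.ensembles:
            if e.format not in {"xyz", "pdb"}:
                raise ConfigError(f"ensembles[{e.label}].format must be xyz or pdb")
            if e.format == "xyz" and not e.n_residues:
                raise ConfigError(f"ensembles[{e.label}].n_residues required for xyz input")


@dataclass
class PipelineReport:
    """Per-ensemble outputs plus the cross-ensemble comparison."""

    per_ensemble: dict[str, dict]
    comparison: pd.DataFrame
    failures: list[tuple[str, str, str]]  # (label, stage, message)
    output_dir: Path


def load_config(path: str) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config field {key!r}")
    ensembles = []
    for i, item in enumerate(raw.pop("ensembles", []) or []):
        for req in ("label", "path"):
            if req not in item:
                raise ConfigError(f"ensembles[{i}].{req} is required")
        unknown = set(item) - set(EnsembleInput.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"ensembles[{i}]: unknown fields {sorted(unknown)}")
        ensembles.append(EnsembleInput(**item))
    for tup in ("loop1", "loop2", "gap_residues", "pocket_thresholds"):
        if tup in raw:
            raw[tup] = tuple(raw[tup])
    cfg = AnalysisConfig(ensembles=ensembles, **raw)
    cfg.validate()
    return cfg


def _load_ensemble(ens: EnsembleInput) -> TrajectoryEnsemble:
    if ens.format == "pdb":
        return read_multimodel_pdb(ens.path)
    topology = make_calpha_topology(ens.n_residues)
    return read_xyz_trajectory(ens.path, topology)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Run every analysis stage on every configured ensemble.

    Outputs under ``output_dir/<label>/``: ``rmsf.csv``, ``eigenvalues.csv``,
    ``projections.csv``, ``fel_grid.csv``, ``basins.csv``, ``dccm.csv``,
    ``occupancy.csv``, ``gap.csv`` and ``summary.txt``; plus
    ``comparison.csv`` and ``run.log`` at the top level. Failed stages are
    recorded in the report and logged; independent stages still run.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    per_ensemble: dict[str, dict] = {}
    failures: list[tuple[str, str, str]] = []
    comparison_rows = []
    try:
        logger.info("loopgate %s python %s", __version__, platform.python_version())
        logger.info("effective config: %s", json.dumps(asdict(config), default=str))
        for ens in config.ensembles:
            label = ens.label
            results: dict = {}
            per_ensemble[label] = results
            ensdir = outdir / label
            ensdir.mkdir(parents=True, exist_ok=True)
            logger.info("[%s] loading %s (%s)", label, ens.path, ens.format)
            try:
                traj = _load_ensemble(ens)
            except LoopgateError as exc:
                logger.error("[%s] load failed: %s", label, exc)
                failures.append((label, "load", str(exc)))
                continue

            fit_sel = select_atoms(traj, config.fit_selection)
            ana_sel = select_atoms(traj, config.analysis_selection)
            fitted = iterative_mean_fit(traj, fit_sel).rotated_trajectory

            def stage(name, fn, _label=label):
                try:
                    return fn()
                except LoopgateError as exc:
                    logger.error("[%s] stage %s failed: %s", _label, name, exc)
                    failures.append((_label, name, str(exc)))
                    return None

            profile = stage("rmsf", lambda: compute_rmsf(fitted, ana_sel, prefit=False))
            if profile is not None:
                results["rmsf"] = profile
                _write_csv(
                    pd.DataFrame({"residue": profile.residue_numbers, "rmsf_A": profile.rmsf}),
                    ensdir / "rmsf.csv",
                )

            model = stage("pca", lambda: build_covariance(fitted, ana_sel, prefit=False))
            proj = surface = basins = None
            if model is not None:
                results["covariance"] = model
                _write_csv(
                    pd.DataFrame({"mode": np.arange(1, model.eigenvalues.size + 1),
                                  "eigenvalue_A2": model.eigenvalues}),
                    ensdir / "eigenvalues.csv",
                )
                proj = stage("project", lambda: project(fitted, model))
            if proj is not None:
                results["projections"] = proj
                _write_csv(
                    pd.DataFrame({"frame": np.arange(proj.n_frames),
                                  "pc1_A": proj.pc1, "pc2_A": proj.pc2}),
                    ensdir / "projections.csv",
                )
                surface = stage(
                    "fel",
                    lambda: build_landscape(proj, temperature=config.temperature,
                                            n_bins=config.fel_bins),
                )
            if surface is not None:
                results["fel"] = surface
                grid = pd.DataFrame(surface.delta_g.filled(np.nan))
                grid.to_csv(ensdir / "fel_grid.csv", index=False, float_format="%.6f")
                basins = stage(
                    "basins",
                    lambda: count_basins(surface, config.basin_depth_cutoff,
                                         config.basin_min_separation),
                )
            if basins is not None:
                results["basins"] = basins
                _write_csv(
                    pd.DataFrame(
                        [(b.center[0], b.center[1], b.delta_g) for b in basins],
                        columns=["pc1_A", "pc2_A", "delta_g_kcal_mol"],
                    ),
                    ensdir / "basins.csv",
                )

            dccm = stage("dccm", lambda: compute_dccm(fitted, ana_sel, prefit=False))
            block_score = None
            if dccm is not None:
                results["dccm"] = dccm
                pd.DataFrame(dccm.values.filled(np.nan)).to_csv(
                    ensdir / "dccm.csv", index=False, float_format="%.6f"
                )
                block_score = stage(
                    "block_score",
                    lambda: block_correlation_score(dccm, config.loop1, config.loop2),
                )
                results["block_score"] = block_score

            criteria = HBondCriteria(donor_acceptor_cutoff=config.hbond_cutoff)
            lig_sel = stage("hbond", lambda: select_atoms(traj, config.ligand_selection))
            table = None
            if lig_sel is not None and len(lig_sel) > 0:
                prot_sel = select_atoms(traj, config.protein_polar_selection)
                table = stage(
                    "hbond",
                    lambda: occupancy_table(
                        fitted, lig_sel, prot_sel, criteria,
                        min_occupancy=config.hbond_min_occupancy,
                        skip_frames=config.hbond_skip_frames,
                    ),
                )
            if table is not None:
                results["occupancy"] = table
                _write_csv(table.to_dataframe(), ensdir / "occupancy.csv")

            gap = stage("gap", lambda: loop_gap_series(fitted, *config.gap_residues))
            modal_state = None
            extreme_gap = None
            if gap is not None:
                results["gap"] = gap
                _write_csv(
                    pd.DataFrame({"frame": np.arange(gap.values.size), "gap_A": gap.values}),
                    ensdir / "gap.csv",
                )
                states = [
                    classify_pocket_state(g, config.pocket_thresholds).state
                    for g in gap.values
                ]
                modal_state = Counter(states).most_common(1)[0][0]
                results["modal_state"] = modal_state
                if proj is not None:
                    extreme_gap = float(gap.values[extreme_frame(proj, mode=1, side="max")])
                    results["extreme_frame_gap"] = extreme_gap

            with open(ensdir / "summary.txt", "w") as fh:
                fh.write(f"ensemble: {label}\n")
                fh.write(f"frames: {traj.n_frames}  atoms: {traj.n_atoms}\n")
                if model is not None:
                    fh.write(f"eigenvalue1_A2: {model.eigenvalues[0]:.4f}\n")
                if basins is not None:
                    fh.write(f"basin_count: {len(basins)}\n")
                if block_score is not None:
                    fh.write(f"loop_block_score: {block_score:.4f}\n")
                if modal_state is not None:
                    fh.write(f"modal_pocket_state: {modal_state}\n")

            comparison_rows.append(
                {
                    "label": label,
                    "n_frames": traj.n_frames,
                    "basin_count": len(basins) if basins is not None else np.nan,
                    "loop_block_score": block_score if block_score is not None else np.nan,
                    "modal_pocket_state": modal_state or "",
                    "max_pc1_frame_gap_A": extreme_gap if extreme_gap is not None else np.nan,
                }
            )

        comparison = pd.DataFrame(comparison_rows)
        if not comparison.empty:
            _write_csv(comparison, outdir / "comparison.csv")
        logger.info("pipeline finished with %d stage failure(s)", len(failures))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return PipelineReport(
        per_ensemble=per_ensemble,
        comparison=comparison,
        failures=failures,
        output_dir=outdir,
    )


# ---------------------------------------------------------------------------
# Synthetic-ensemble simulation from spec files
# ---------------------------------------------------------------------------

_SIM_KINDS = {"gating", "gaussian", "hbond_pair"}


def simulate_from_spec(spec_path: str, output_path: str, seed: int | None = None) -> dict:
    """Generate a synthetic ensemble from a YAML spec file and write it as XYZ.

    The spec file carries ``kind`` (``gating`` | ``gaussian`` | ``hbond_pair``)
    plus the generator's keyword fields. A manifest JSON recording the spec,
    the effective seed and the output path is written next to the trajectory.
    Returns the manifest dict.
    """
    with open(spec_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("simulation spec root must be a mapping")
    kind = raw.pop("kind", None)
    if kind is None:
        raise ConfigError("missing required field 'kind'")
    if kind not in _SIM_KINDS:
        raise ConfigError(f"kind: must be one of {sorted(_SIM_KINDS)}, got {kind!r}")
    if seed is not None:
        raw["seed"] = int(seed)

    try:
        if kind == "gating":
            for tup in ("loop1", "loop2"):
                if tup in raw:
                    raw[tup] = tuple(raw[tup])
            traj = generate_two_loop_gating_ensemble(**raw)
        elif kind == "gaussian":
            spec = GaussianEnsembleSpec(
                mean_structure=np.asarray(raw.pop("mean_structure")),
                **raw,
            )
            traj = generate_gaussian_ensemble(spec)
        else:
            traj = hbond_pair_ensemble(HBondSeriesSpec(**raw))
    except TypeError as exc:
        raise ConfigError(f"{kind}: {exc}") from exc

    write_xyz_trajectory(traj, output_path)
    manifest = {
        "kind": kind,
        "spec": {k: v for k, v in raw.items() if not isinstance(v, np.ndarray)},
        "seed": raw.get("seed", 0),
        "output": str(output_path),
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "loopgate_version": __version__,
    }
    manifest_path = Path(str(output_path) + ".manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
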