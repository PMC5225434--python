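import numpy as np
import pytest

from loopgate import (
    GaussianEnsembleSpec,
    TrajectoryEnsemble,
    generate_gaussian_ensemble,
    helical_mean_structure,
    make_calpha_topology,
)


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  record="ATOM", altloc=" ", occupancy=1.0, element=None):
    """One fixed-column PDB ATOM/HETATM record."""
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {name_field:<4s}{altloc}{resname:<3s} "
        f"{chain}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_model_pdb(tmp_path):
    """A 2-MODEL, 3-atom PDB file (protein + one ligand het atom)."""
    lines = []
    for m, shift in ((1, 0.0), (2, 1.5)):
        lines.append(f"MODEL     {m:4d}")
        lines.append(pdb_atom_line(1, "CA", "ASN", "A", 33, 11.0 + shift, 6.0, -6.5))
        lines.append(pdb_atom_line(2, "OD1", "ASN", "A", 33, 12.0 + shift, 7.0, -6.0, element="O"))
        lines.append(pdb_atom_line(3, "N4", "TH2", "A", 900, 14.0 + shift, 6.5, -5.0,
                                   record="HETATM", element="N"))
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def random_ensemble():
    """A small helical Gaussian ensemble with isotropic noise."""
    spec = GaussianEnsembleSpec(
        mean_structure=helical_mean_structure(10),
        isotropic_noise_sigma=0.5,
        n_frames=40,
        seed=7,
    )
    return generate_gaussian_ensemble(spec)


def straight_chain(n_residues, n_frames=1, spacing=3.8):
    """Collinear Cα chain along x (constant over frames)."""
    coords = np.zeros((n_frames, n_residues, 3))
    coords[:, :, 0] = spacing * np.arange(n_residues)
    return TrajectoryEnsemble(atoms=make_calpha_topology(n_residues), coordinates=coords)
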