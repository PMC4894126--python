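import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, element=None):
    """One correctly column-aligned PDB ATOM record."""
    element = element or name.strip()[0]
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Minimal 2-chain, 5-residue-per-chain Cα-only PDB file."""
    lines = []
    serial = 1
    for ci, chain in enumerate("AB"):
        for r in range(1, 6):
            lines.append(
                pdb_atom_line(
                    serial, "CA", "GLY", chain, r,
                    (float(r), float(ci), 0.0), "C",
                )
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gapped_pdb(tmp_path):
    """Two chains where chain B lacks residue 3."""
    lines = []
    serial = 1
    for chain, residues in (("A", (1, 2, 3, 4, 5)), ("B", (1, 2, 4, 5))):
        for r in residues:
            lines.append(
                pdb_atom_line(
                    serial, "CA", "GLY", chain, r,
                    (float(r), 0.0, 0.0), "C",
                )
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path = tmp_path / "gapped.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
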