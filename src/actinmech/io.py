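"""Structure and trajectory I/O.

PDB files are read and written through Biopython (author residue
numbering, ATOM records only); trajectories use two plain-text dialects:

* multi-frame XYZ — repeated blocks of ``n``, a comment line, then ``n``
  lines of ``atom x y z`` (Å);
* trajectory CSV — columns ``frame, subunit, residue, atom, x, y, z``.

All files are UTF-8.
"""

from __future__ import annotations

import string
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder

from .core import (
    ChainTrace,
    FilamentModel,
    MissingResidueError,
    Trajectory,
)

__all__ = [
    "read_structure",
    "read_subunit",
    "write_structure",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_csv_trajectory",
    "write_csv_trajectory",
]


def _chain_to_subunit_dict(chain, residue_offset: int, allow_gaps: bool):
    sub: dict[int, dict[str, np.ndarray]] = {}
    elements: dict[str, str] = {}
    for residue in chain:
        hetflag = residue.id[0]
        if hetflag.strip():  # heteroatoms and waters excluded
            continue
        resid = residue.id[1] + residue_offset
        atoms = {}
        for atom in residue:
            atoms[atom.get_name()] = np.asarray(atom.coord, dtype=float)
            if atom.element:
                elements[atom.get_name()] = atom.element
        if atoms:
            sub[resid] = atoms
    if not sub:
        raise MissingResidueError(f"chain {chain.id!r} contains no ATOM records")
    if not allow_gaps:
        lo, hi = min(sub), max(sub)
        missing = [r for r in range(lo, hi + 1) if r not in sub]
        if missing:
            raise MissingResidueError(
                f"chain {chain.id!r} is missing coordinates for residue(s) "
                f"{missing}"
            )
    return sub, elements


def read_structure(
    path,
    chain_to_subunit: str = "chain",
    residue_offset: int = 0,
    allow_gaps: bool = False,
) -> FilamentModel:
    """Read a multi-subunit filament from a PDB file.

    Each chain (``chain_to_subunit="chain"``, default) or each MODEL
    (``"model"``) becomes one subunit, in file order.  Author residue
    numbers are taken at face value; ``residue_offset`` is added for
    structures not numbered on the mature-actin convention.  Heteroatoms
    and waters are excluded.

    Raises
    ------
    MissingResidueError
        If a chain has a residue gap (unless ``allow_gaps``) or the
        subunits do not expose identical residue sets.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate fixture PDBs without headers
        structure = PDBParser(QUIET=True).get_structure("filament", str(path))
    subunits = []
    elements: dict[str, str] = {}
    if chain_to_subunit == "model":
        units = [chain for model in structure for chain in model]
    elif chain_to_subunit == "chain":
        units = list(next(iter(structure)))
    else:
        raise ValueError(f"unknown chain_to_subunit rule {chain_to_subunit!r}")
    if not units:
        raise MissingResidueError(f"{path}: no chains found")
    for chain in units:
        sub, elem = _chain_to_subunit_dict(chain, residue_offset, allow_gaps)
        subunits.append(sub)
        elements.update(elem)
    if len(subunits) == 1:
        raise ValueError(
            f"{path} holds a single subunit; use read_subunit() and "
            "build_ideal_filament() to replicate it into a filament"
        )
    return FilamentModel(subunits, elements=elements)


def read_subunit(path, chain: str | None = None, residue_offset: int = 0,
                 allow_gaps: bool = False):
    """Read one chain of a PDB file as a residue->atom coordinate table.

    Intended for single-subunit structures (a 2ZWH-style monomer) that are
    then replicated with :func:`actinmech.core.build_ideal_filament`.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("subunit", str(path))
    chains = list(next(iter(structure)))
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise MissingResidueError(f"{path}: no chain {chain!r}")
    sub, _ = _chain_to_subunit_dict(chains[0], residue_offset, allow_gaps)
    return sub


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def write_structure(model: FilamentModel, path) -> None:
    """Write a FilamentModel as a PDB file (one chain per subunit)."""
    if model.n_subunits > len(_CHAIN_IDS):
        raise ValueError("too many subunits for PDB chain identifiers")
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("filament")
    builder.init_model(0)
    serial = 1
    for si, sub in enumerate(model.subunits):
        builder.init_chain(_CHAIN_IDS[si])
        builder.init_seg("    ")
        for resid in sorted(sub):
            builder.init_residue("GLY", " ", resid, " ")
            for name, xyz in sub[resid].items():
                element = model.elements.get(name) or name.strip()[:1].upper()
                builder.init_atom(
                    name,
                    np.asarray(xyz, dtype=float),
                    0.0,
                    1.0,
                    " ",
                    name.center(4)[:4],
                    serial,
                    element=element,
                )
                serial += 1
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    pdbio.save(str(path))


def write_xyz_trajectory(traj: Trajectory, path, label: str = "X") -> None:
    """Write ChainTrace frames in the multi-frame XYZ dialect."""
    nodes = traj.node_array()
    with open(path, "w", encoding="utf-8") as fh:
        for fi, frame in enumerate(nodes):
            fh.write(f"{frame.shape[0]}\nframe {fi}\n")
            for x, y, z in frame:
                fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(path) -> Trajectory:
    """Read a multi-frame XYZ file as a trajectory of chain traces."""
    frames: list[ChainTrace] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise ValueError(f"{path}: truncated XYZ frame at line {i + 1}")
        nodes = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(ChainTrace(nodes))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(frames)


def write_csv_trajectory(traj: Trajectory, path) -> None:
    """Write FilamentModel frames as the flat trajectory CSV dialect."""
    rows = []
    for fi, frame in enumerate(traj.frames):
        for si, sub in enumerate(frame.subunits):
            for resid in sorted(sub):
                for atom, xyz in sub[resid].items():
                    rows.append((fi, si, resid, atom, *xyz))
    pd.DataFrame(
        rows, columns=["frame", "subunit", "residue", "atom", "x", "y", "z"]
    ).to_csv(path, index=False)


def read_csv_trajectory(path) -> Trajectory:
    """Read the trajectory CSV dialect into FilamentModel frames."""
    df = pd.read_csv(path)
    required = {"frame", "subunit", "residue", "atom", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frames = []
    for _, fdf in df.groupby("frame", sort=True):
        subunits = []
        for _, sdf in fdf.groupby("subunit", sort=True):
            sub: dict[int, dict[str, np.ndarray]] = {}
            for row in sdf.itertuples(index=False):
                sub.setdefault(int(row.residue), {})[str(row.atom)] = np.array(
                    [row.x, row.y, row.z], dtype=float
                )
            subunits.append(sub)
        frames.append(FilamentModel(subunits))
    return Trajectory(frames)
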