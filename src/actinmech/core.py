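"""Domain types and geometric primitives for actin-filament analysis.

The filament is described on the *genetic* (one-start) helix: subunit
``i`` sits one axial rise above subunit ``i-1`` and is rotated by the
helical twist about the filament axis (~27.5 Å and ~-166° for F-actin, the
negative sign marking the left-handed genetic helix).  Long-pitch strand
neighbours are therefore subunits ``i`` and ``i+2``.

Coordinates are in Å throughout; persistence lengths are converted to μm
only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ActinMechError",
    "MissingResidueError",
    "DegenerateGeometryError",
    "ResidueGroupSpec",
    "SG1",
    "SG2",
    "SG3",
    "SG4",
    "D_LOOP",
    "STANDARD_GROUPS",
    "FilamentModel",
    "ChainTrace",
    "Trajectory",
    "build_ideal_filament",
    "cog",
    "axis_trace",
]

N_ACTIN_RESIDUES = 375

# Conversion used at the reporting layer only.
ANGSTROM_PER_MICROMETRE = 1.0e4


class ActinMechError(Exception):
    """Base class for all errors raised by this package."""


class MissingResidueError(ActinMechError):
    """A requested residue has no coordinates in a subunit."""


class DegenerateGeometryError(ActinMechError):
    """Geometry is degenerate (coincident points, collinear triples, ...)."""


@dataclass(frozen=True)
class ResidueGroupSpec:
    """A named set of residues given as inclusive 1-based index intervals.

    Residue numbering follows mature skeletal α-actin (1..375), the
    convention in which H40 lies inside the D-loop (residues 38-52).

    Parameters
    ----------
    name : str
        Short label, e.g. ``"SG1"`` or ``"D-loop"``.
    ranges : tuple of (lo, hi)
        Non-overlapping inclusive intervals with ``1 <= lo <= hi <= 375``.
    """

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError(f"group {self.name!r}: ranges must be non-empty")
        seen: set[int] = set()
        for lo, hi in self.ranges:
            if not (1 <= lo <= hi <= N_ACTIN_RESIDUES):
                raise ValueError(
                    f"group {self.name!r}: interval ({lo}, {hi}) outside "
                    f"1..{N_ACTIN_RESIDUES} or inverted"
                )
            ids = set(range(lo, hi + 1))
            if ids & seen:
                raise ValueError(f"group {self.name!r}: overlapping intervals")
            seen |= ids

    @property
    def residues(self) -> tuple[int, ...]:
        """All residue indices in the group, ascending."""
        out: list[int] = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return tuple(sorted(out))

    def __contains__(self, residue: int) -> bool:
        return any(lo <= residue <= hi for lo, hi in self.ranges)


# Rigid sub-groups used for the coarse-grained subunit geometry; their
# centres of geometry are denoted R1..R4.
SG1 = ResidueGroupSpec("SG1", ((5, 33), (80, 147), (334, 349)))
SG2 = ResidueGroupSpec("SG2", ((34, 39), (52, 59)))
SG3 = ResidueGroupSpec("SG3", ((148, 179), (273, 333)))
SG4 = ResidueGroupSpec("SG4", ((180, 219), (252, 262)))
D_LOOP = ResidueGroupSpec("D-loop", ((38, 52),))

STANDARD_GROUPS: dict[str, ResidueGroupSpec] = {
    g.name: g for g in (SG1, SG2, SG3, SG4, D_LOOP)
}


def _as_point(value) -> np.ndarray:
    pt = np.asarray(value, dtype=float)
    if pt.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {pt.shape}")
    if not np.all(np.isfinite(pt)):
        raise ValueError("coordinates must be finite")
    return pt


def _is_hydrogen(atom_name: str, element: str | None = None) -> bool:
    if element:
        return element.strip().upper() == "H"
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() == "H"


# A subunit is a mapping residue-index -> {atom name -> xyz (Å)}.
SubunitCoords = Mapping[int, Mapping[str, np.ndarray]]


class FilamentModel:
    """An n-subunit helical filament with per-residue atomic coordinates.

    Subunits are ordered along the genetic helix (index 0..n-1).  Every
    subunit must expose the same residue-index set.

    Parameters
    ----------
    subunits : sequence of mappings
        ``subunits[i][residue][atom]`` is a 3-vector in Å.
    axial_repeat : float, optional
        Axial box length (Å) after which the filament repeats (``n * rise``
        for an ideal filament under periodic boundary conditions).
    elements : mapping, optional
        Optional atom-name -> element map used to exclude hydrogens.
    """

    def __init__(
        self,
        subunits: Sequence[SubunitCoords],
        axial_repeat: float | None = None,
        elements: Mapping[str, str] | None = None,
    ) -> None:
        if len(subunits) < 2:
            raise ValueError("a filament needs at least 2 subunits")
        canon = None
        store: list[dict[int, dict[str, np.ndarray]]] = []
        for si, sub in enumerate(subunits):
            resset = frozenset(sub.keys())
            if canon is None:
                canon = resset
            elif resset != canon:
                missing = sorted(canon ^ resset)
                raise MissingResidueError(
                    f"subunit {si} residue set differs from subunit 0 "
                    f"(residues {missing})"
                )
            store.append(
                {
                    int(r): {a: _as_point(x) for a, x in atoms.items()}
                    for r, atoms in sub.items()
                }
            )
        self.subunits = store
        self.axial_repeat = axial_repeat
        self.elements = dict(elements) if elements else {}

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.subunits[0]))

    @classmethod
    def from_points(
        cls, points: np.ndarray, axial_repeat: float | None = None
    ) -> "FilamentModel":
        """Build a point-subunit filament (one CA pseudo-atom per subunit)."""
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must have shape (n_subunits, 3)")
        return cls([{1: {"CA": p}} for p in points], axial_repeat=axial_repeat)

    def atom_coords(
        self,
        subunit: int,
        group: ResidueGroupSpec | None = None,
        representation: str = "heavy",
    ) -> np.ndarray:
        """Coordinates of the selected atoms of one subunit, shape (m, 3).

        ``representation`` is ``"heavy"`` (all non-hydrogen atoms, default),
        ``"ca"`` (Cα only) or ``"all"``.
        """
        sub = self.subunits[subunit]
        residues = group.residues if group is not None else sorted(sub)
        rows: list[np.ndarray] = []
        for r in residues:
            if r not in sub:
                where = f"group {group.name!r}" if group is not None else "selection"
                raise MissingResidueError(
                    f"residue {r} ({where}) missing from subunit {subunit}"
                )
            for name, xyz in sub[r].items():
                if representation == "ca":
                    if name.strip().upper() != "CA":
                        continue
                elif representation == "heavy":
                    if _is_hydrogen(name, self.elements.get(name)):
                        continue
                elif representation != "all":
                    raise ValueError(f"unknown representation {representation!r}")
                rows.append(xyz)
        if not rows:
            raise DegenerateGeometryError(
                f"empty atom selection for subunit {subunit} "
                f"(group={getattr(group, 'name', None)!r}, "
                f"representation={representation!r})"
            )
        return np.vstack(rows)

    def residue_coord(
        self, subunit: int, residue: int, representation: str = "ca"
    ) -> np.ndarray:
        """Single-point representation of one residue (Cα or heavy-atom COG)."""
        sub = self.subunits[subunit]
        if residue not in sub:
            raise MissingResidueError(
                f"residue {residue} missing from subunit {subunit}"
            )
        atoms = sub[residue]
        if representation == "ca":
            for name, xyz in atoms.items():
                if name.strip().upper() == "CA":
                    return xyz
            raise MissingResidueError(
                f"residue {residue} of subunit {subunit} has no CA atom"
            )
        if representation == "cog":
            pts = [
                xyz
                for name, xyz in atoms.items()
                if not _is_hydrogen(name, self.elements.get(name))
            ]
            if not pts:
                raise DegenerateGeometryError(
                    f"residue {residue} of subunit {subunit} has no heavy atoms"
                )
            return np.mean(pts, axis=0)
        raise ValueError(f"unknown residue representation {representation!r}")


@dataclass
class ChainTrace:
    """An ordered polygonal trace of a filament (e.g. subunit COGs).

    Attributes
    ----------
    nodes : ndarray, shape (n, 3)
        Node positions in Å, in genetic-helix order.
    """

    nodes: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must have shape (n, 3)")
        if len(self.nodes) < 3:
            raise ValueError("a chain trace needs at least 3 nodes")
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise DegenerateGeometryError("coincident consecutive nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def b(self) -> float:
        """Mean segment length (Å)."""
        return float(
            np.mean(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1))
        )

    def tangents(self) -> np.ndarray:
        """Unit tangent vectors, shape (n-1, 3)."""
        d = np.diff(self.nodes, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class Trajectory:
    """An ordered ensemble of conformations (FilamentModel or ChainTrace).

    Frames must be structurally congruent: same node count for traces,
    same subunit/residue sets for filaments.
    """

    frames: list
    frame_interval: float | None = None  # ns per frame, if known

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        first = self.frames[0]
        if isinstance(first, ChainTrace):
            n = first.n_nodes
            if any(f.n_nodes != n for f in self.frames):
                raise ValueError("all frames must have the same node count")
        elif isinstance(first, FilamentModel):
            n = first.n_subunits
            res = first.residues
            for f in self.frames:
                if f.n_subunits != n or f.residues != res:
                    raise ValueError(
                        "all frames must share subunit and residue sets"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def node_array(self) -> np.ndarray:
        """Stack ChainTrace frames into an array of shape (F, n, 3)."""
        if not isinstance(self.frames[0], ChainTrace):
            raise TypeError("node_array requires ChainTrace frames")
        return np.stack([f.nodes for f in self.frames])


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_ideal_filament(
    subunit: SubunitCoords,
    n: int,
    rise: float,
    twist: float,
    axis: str = "z",
) -> FilamentModel:
    """Replicate one subunit into an ideal helical filament.

    Subunit ``i`` is the input coordinates rotated by ``i * twist`` about
    the +z axis (right-hand rule; F-actin's left-handed genetic helix has
    negative twist) and translated by ``i * rise`` along z.  The axial
    repeat is ``n * rise``.

    Parameters
    ----------
    subunit : mapping residue -> {atom -> xyz}
    n : int
        Number of subunits (>= 2); 13 gives one F-actin crossover repeat.
    rise : float
        Axial rise per subunit, Å (> 0).
    twist : float
        Signed twist per subunit, degrees, ``|twist| < 360``.
    """
    if axis != "z":
        raise NotImplementedError("only the z axis is supported")
    if n < 2:
        raise ValueError("n must be >= 2")
    if rise <= 0:
        raise ValueError("rise must be positive")
    if abs(twist) >= 360:
        raise ValueError("|twist| must be < 360 degrees")
    base = {
        int(r): {a: _as_point(x) for a, x in atoms.items()}
        for r, atoms in subunit.items()
    }
    subunits = []
    for i in range(n):
        rot = _rotation_about_z(i * twist)
        shift = np.array([0.0, 0.0, i * rise])
        subunits.append(
            {
                r: {a: rot @ xyz + shift for a, xyz in atoms.items()}
                for r, atoms in base.items()
            }
        )
    return FilamentModel(subunits, axial_repeat=n * rise)


def cog(
    model: FilamentModel,
    subunit: int,
    group: ResidueGroupSpec | None = None,
    representation: str = "heavy",
) -> np.ndarray:
    """Centre of geometry (unweighted mean position) of an atom selection.

    This is the plain geometric mean of the selected coordinates — masses
    play no role.  The R1..R4 points of the coarse-grained subunit
    description are COGs of the SG1..SG4 groups.
    """
    return model.atom_coords(subunit, group, representation).mean(axis=0)


def axis_trace(
    model: FilamentModel,
    group: ResidueGroupSpec | None = None,
    representation: str = "heavy",
) -> ChainTrace:
    """Per-subunit COG trace of a filament, in genetic-helix order.

    The result is the discretisation consumed by the persistence-length
    estimator; its ``b`` is the mean consecutive-COG distance (for an
    off-axis COG at radius r this is ``sqrt(rise**2 + (2 r sin(|twist|/2))**2)``,
    the chord geometry of the helix).
    """
    if model.n_subunits < 3:
        raise ValueError("axis_trace needs at least 3 subunits")
    nodes = np.vstack(
        [cog(model, i, group, representation) for i in range(model.n_subunits)]
    )
    return ChainTrace(nodes)
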