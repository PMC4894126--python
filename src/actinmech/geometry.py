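"""Inter-subunit contacts and coarse-grained subunit geometry.

Two families of observables:

* residue-pair distances between a subunit and its neighbours —
  longitudinal contacts pair subunit ``i`` with ``i+2`` (the next subunit
  up the same long-pitch strand), lateral contacts pair ``i`` with
  ``i+1`` (the opposite strand), and intra-subunit pairs use offset 0.
  Residues are represented by their Cα atom by default (``"ca"``) or by
  the residue heavy-atom centre of geometry (``"cog"``).
* a coarse-grained subunit description: the centres of geometry R1..R4
  of the rigid sub-groups SG1..SG4 with the bonds R1-R2, R1-R3, R3-R4,
  the angles R1-R3-R4 and R2-R1-R3, and the dihedral R2-R1-R3-R4.

Ensemble statistics pool all frames and all applicable subunits; quoted
spreads are population standard deviations (switchable to the n-1
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    SG1,
    SG2,
    SG3,
    SG4,
    DegenerateGeometryError,
    FilamentModel,
    ResidueGroupSpec,
    Trajectory,
    cog,
)

__all__ = [
    "ContactSpec",
    "TABLE_CONTACTS",
    "DistanceSummary",
    "pair_distance",
    "equilibrated_distance",
    "contact_table",
    "ContactCount",
    "count_contacts",
    "CGGeometry",
    "cg_geometry",
    "trajectory_cg_summary",
    "read_contact_specs",
    "write_contact_specs",
]

DEFAULT_CUTOFF = 8.0  # Å, Cα-Cα
CG_GROUPS = (SG1, SG2, SG3, SG4)

# Regions of the along-strand (i+2) subunit against which D-loop contacts
# are counted.
D_LOOP_TARGETS = ResidueGroupSpec(
    "D-loop targets", ((130, 150), (161, 175), (345, 357), (369, 375))
)


@dataclass(frozen=True)
class ContactSpec:
    """One monitored residue pair between subunits ``i`` and ``i+offset``."""

    label: str
    residue_a: int
    residue_b: int
    subunit_offset: int = 2
    representation: str = "ca"

    def __post_init__(self) -> None:
        for r in (self.residue_a, self.residue_b):
            if not 1 <= r <= 375:
                raise ValueError(f"residue {r} outside 1..375")
        if self.subunit_offset not in (0, 1, 2):
            raise ValueError("subunit_offset must be 0 (intra), 1 (lateral) "
                             "or 2 (longitudinal)")
        if self.representation not in ("ca", "cog"):
            raise ValueError("representation must be 'ca' or 'cog'")


# The canonical monitored contacts: longitudinal (along-strand, offset +2)
# D-loop and neighbouring-subdomain pairs, plus the lateral H-plug/C-terminus
# pair (offset +1).
TABLE_CONTACTS: tuple[ContactSpec, ...] = (
    ContactSpec("D-loop vs C-term 41-374", 41, 374, 2),
    ContactSpec("D-loop vs C-term 61-374", 61, 374, 2),
    ContactSpec("D-loop vs C-term 45-370", 45, 370, 2),
    ContactSpec("D-loop vs SD1 45-169", 45, 169, 2),
    ContactSpec("D-loop vs SD1 61-169", 61, 169, 2),
    ContactSpec("D-loop vs SD3 62-288", 62, 288, 2),
    ContactSpec("SD4 vs SD3 205-286", 205, 286, 2),
    ContactSpec("SD4 vs SD3 241-322", 241, 322, 2),
    ContactSpec("H-plug vs C 265-374", 265, 374, 1),
)


def read_contact_specs(path) -> list[ContactSpec]:
    """Read the contact-spec CSV dialect: label,res_a,res_b,offset,representation."""
    df = pd.read_csv(path)
    required = {"label", "res_a", "res_b", "offset", "representation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ContactSpec(
            str(r.label), int(r.res_a), int(r.res_b), int(r.offset),
            str(r.representation),
        )
        for r in df.itertuples(index=False)
    ]


def write_contact_specs(specs, path) -> None:
    pd.DataFrame(
        [
            (s.label, s.residue_a, s.residue_b, s.subunit_offset, s.representation)
            for s in specs
        ],
        columns=["label", "res_a", "res_b", "offset", "representation"],
    ).to_csv(path, index=False)


def pair_distance(frame: FilamentModel, spec: ContactSpec, subunit_i: int) -> float:
    """Distance (Å) between residue_a of subunit i and residue_b of i+offset."""
    j = subunit_i + spec.subunit_offset
    if not (0 <= subunit_i < frame.n_subunits and j < frame.n_subunits):
        raise IndexError(
            f"subunit pair ({subunit_i}, {j}) outside filament of "
            f"{frame.n_subunits} subunits"
        )
    a = frame.residue_coord(subunit_i, spec.residue_a, spec.representation)
    b = frame.residue_coord(j, spec.residue_b, spec.representation)
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceSummary:
    """Equilibrated (ensemble mean) distance with its SD."""

    label: str
    mean: float
    sd: float
    n_samples: int


def equilibrated_distance(
    traj: Trajectory, spec: ContactSpec, ddof: int = 0
) -> DistanceSummary:
    """Mean and SD of a contact distance over all frames and subunits.

    ``ddof=0`` (population SD) is the default convention for pooled
    frame × subunit samples; pass ``ddof=1`` for the sample SD.
    """
    samples = []
    for frame in traj.frames:
        n_apply = frame.n_subunits - spec.subunit_offset
        if n_apply < 1:
            raise ValueError(
                f"offset {spec.subunit_offset} exceeds filament of "
                f"{frame.n_subunits} subunits"
            )
        for i in range(n_apply):
            samples.append(pair_distance(frame, spec, i))
    arr = np.asarray(samples)
    return DistanceSummary(
        label=spec.label,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0,
        n_samples=len(arr),
    )


def contact_table(
    traj: Trajectory, specs=TABLE_CONTACTS, ddof: int = 0
) -> pd.DataFrame:
    """Equilibrated-distance table for a list of contact specs."""
    rows = [equilibrated_distance(traj, s, ddof=ddof) for s in specs]
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "mean_A": [r.mean for r in rows],
            "sd_A": [r.sd for r in rows],
            "n": [r.n_samples for r in rows],
        }
    )


@dataclass
class ContactCount:
    """Number of residue pairs within a cutoff, per applicable subunit."""

    range_a: ResidueGroupSpec
    range_b: ResidueGroupSpec
    subunit_offset: int
    cutoff: float
    counts: np.ndarray  # one integer per applicable subunit index
    mean_count: float


def count_contacts(
    frame: FilamentModel,
    range_a: ResidueGroupSpec,
    range_b: ResidueGroupSpec,
    subunit_offset: int = 2,
    cutoff: float = DEFAULT_CUTOFF,
    representation: str = "ca",
) -> ContactCount:
    """Count residue pairs of (i, i+offset) subunits within a cutoff.

    A pair (a in range_a of subunit i, b in range_b of subunit
    i+offset) counts when its representation distance is <= cutoff; the
    count is averaged over every applicable subunit i.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_apply = frame.n_subunits - subunit_offset
    if n_apply < 1:
        raise ValueError("offset exceeds the filament length")
    res_a = range_a.residues
    res_b = range_b.residues
    counts = np.zeros(n_apply, dtype=int)
    for i in range(n_apply):
        pa = np.vstack(
            [frame.residue_coord(i, r, representation) for r in res_a]
        )
        pb = np.vstack(
            [
                frame.residue_coord(i + subunit_offset, r, representation)
                for r in res_b
            ]
        )
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        counts[i] = int(np.sum(d <= cutoff))
    return ContactCount(
        range_a=range_a,
        range_b=range_b,
        subunit_offset=subunit_offset,
        cutoff=cutoff,
        counts=counts,
        mean_count=float(counts.mean()),
    )


# ---------------------------------------------------------------------------
# Coarse-grained subunit geometry
# ---------------------------------------------------------------------------

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle A-B-C at vertex B, degrees in [0, 180]."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident points in angle")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion of four points, IUPAC convention, degrees (-180, 180].

    Looking from p2 toward p3, the angle from the projection of p1 to the
    projection of p4, positive clockwise.
    """
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise DegenerateGeometryError("collinear points in dihedral")
    y = np.cross(n1, n2) @ (b2 / nb2)
    x = n1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass
class CGGeometry:
    """Coarse-grained geometry of one subunit (R1..R4 = COGs of SG1..SG4)."""

    r: np.ndarray  # shape (4, 3): R1..R4
    bond_r1_r2: float
    bond_r1_r3: float
    bond_r3_r4: float
    angle_r1_r3_r4: float
    angle_r2_r1_r3: float
    dihedral_r2_r1_r3_r4: float

    # Row order of the summary table.
    PARAMETERS = (
        ("bond (A)", "R1-R2", "bond_r1_r2"),
        ("bond (A)", "R1-R3", "bond_r1_r3"),
        ("bond (A)", "R3-R4", "bond_r3_r4"),
        ("angle (deg)", "R1-R3-R4", "angle_r1_r3_r4"),
        ("angle (deg)", "R2-R1-R3", "angle_r2_r1_r3"),
        ("dihedral (deg)", "R2-R1-R3-R4", "dihedral_r2_r1_r3_r4"),
    )


def cg_geometry(
    frame: FilamentModel,
    subunit_i: int,
    groups=CG_GROUPS,
    representation: str = "heavy",
) -> CGGeometry:
    """Coarse-grained bonds/angles/dihedral of one subunit."""
    if len(groups) != 4:
        raise ValueError("exactly four residue groups (SG1..SG4) are required")
    r = np.vstack(
        [cog(frame, subunit_i, g, representation) for g in groups]
    )
    r1, r2, r3, r4 = r
    return CGGeometry(
        r=r,
        bond_r1_r2=float(np.linalg.norm(r1 - r2)),
        bond_r1_r3=float(np.linalg.norm(r1 - r3)),
        bond_r3_r4=float(np.linalg.norm(r3 - r4)),
        angle_r1_r3_r4=_angle(r1, r3, r4),
        angle_r2_r1_r3=_angle(r2, r1, r3),
        dihedral_r2_r1_r3_r4=_dihedral(r2, r1, r3, r4),
    )


def trajectory_cg_summary(
    traj: Trajectory,
    groups=CG_GROUPS,
    representation: str = "heavy",
    ddof: int = 0,
) -> pd.DataFrame:
    """Mean and SD of each CG parameter over frames × subunits.

    Rows follow the conventional order R1-R2, R1-R3, R3-R4, R1-R3-R4,
    R2-R1-R3, R2-R1-R3-R4 with bond/angle/dihedral section labels.
    """
    values = {attr: [] for _, _, attr in CGGeometry.PARAMETERS}
    for frame in traj.frames:
        for i in range(frame.n_subunits):
            g = cg_geometry(frame, i, groups, representation)
            for _, _, attr in CGGeometry.PARAMETERS:
                values[attr].append(getattr(g, attr))
    rows = []
    for section, name, attr in CGGeometry.PARAMETERS:
        arr = np.asarray(values[attr])
        sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        rows.append((section, name, float(arr.mean()), sd, len(arr)))
    return pd.DataFrame(
        rows, columns=["section", "parameter", "mean", "sd", "n"]
    )
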