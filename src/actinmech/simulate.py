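"""Synthetic-data generators.

Each generator is a pure, seeded function of its parameter object and
emulates the statistical structure one analysis stage assumes:

* :func:`generate_wlc_trajectory` — discrete worm-like chains with a
  prescribed persistence length, for the tangent-correlation estimator;
* :func:`generate_helix_ensemble` — point-subunit helical lattices with
  set rise/twist plus isotropic Gaussian thermal noise, for the helical
  symmetry estimator;
* :func:`generate_peak_profile` — Gaussian reflections (optionally a
  two-population composite) on a sloping background with additive
  Gaussian noise, for the sub-pixel peak fit;
* :func:`generate_speed_sample` — one- or two-component Gaussian speed
  mixtures truncated at zero, for the motility statistics;
* :func:`generate_filament_ensemble` — full-residue filaments built
  from a (possibly synthetic) subunit, for the contact/CG geometry
  stage.

These are statistical stand-ins, not physical models: frames are
independent unless the AR(1) knob ``rho`` is set, noise is isotropic and
Gaussian, and the mutation of interest enters only as different
parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .core import (
    ChainTrace,
    FilamentModel,
    Trajectory,
    build_ideal_filament,
    _rotation_about_z,
)
from .motility import SpeedSample
from .xray import Calibration, IntensityProfile

__all__ = [
    "WLCParams",
    "generate_wlc_trajectory",
    "HelixEnsembleParams",
    "ideal_helix_points",
    "generate_helix_ensemble",
    "PeakSimParams",
    "generate_peak_profile",
    "SpeedSimParams",
    "generate_speed_sample",
    "synthetic_subunit",
    "generate_filament_ensemble",
]

_THETA_GRID_STEP = 1e-4  # rad; inverse-CDF grid resolution for bend angles


# ---------------------------------------------------------------------------
# Worm-like chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WLCParams:
    """Discrete worm-like-chain ensemble parameters.

    ``lp`` and ``b`` are in Å (55 Å is the F-actin subunit-COG node
    spacing used throughout).  ``rho`` optionally couples successive
    frames through an AR(1) Gaussian copula on the bend-angle draws so
    that block averaging has something nontrivial to do; the default 0
    keeps frames independent.
    """

    n_nodes: int
    b: float
    lp: float
    n_frames: int
    seed: int
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.b <= 0 or self.lp <= 0:
            raise ValueError("b and lp must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


def _bend_angle_inverse_cdf(lp: float, b: float):
    """Tabulated inverse CDF of the bend-angle density on [0, pi].

    The density is ``f(theta) ∝ exp(-Lp theta^2 / (2 b)) sin(theta)``:
    a harmonic bending energy with the spherical ``sin`` measure.  A
    dense grid makes the sampling rejection-free and reproducible.
    """
    theta = np.linspace(0.0, np.pi, int(np.pi / _THETA_GRID_STEP) + 1)
    with np.errstate(divide="ignore"):
        logf = -lp * theta**2 / (2.0 * b) + np.log(
            np.maximum(np.sin(theta), 0.0)
        )
    logf[0] = -np.inf
    logf[-1] = -np.inf
    f = np.exp(logf - logf.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]))])
    cdf /= cdf[-1]
    return theta, cdf


def _ar1_uniforms(rng, shape, rho) -> np.ndarray:
    """Uniform(0,1) draws, AR(1)-correlated along axis 0 when rho > 0."""
    z = rng.standard_normal(shape)
    if rho > 0:
        out = np.empty_like(z)
        out[0] = z[0]
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, shape[0]):
            out[t] = rho * out[t - 1] + scale * z[t]
        z = out
    return ndtr(z)


def generate_wlc_trajectory(p: WLCParams) -> Trajectory:
    """Sample an ensemble of discrete worm-like chains.

    Each frame starts along +z; successive unit tangents are related by
    a polar bend drawn from the tabulated density (azimuth uniform), so
    ``<t_i . t_{i+k}> = <cos theta>^k ≈ exp(-k b / Lp)``.
    """
    rng = np.random.default_rng(p.seed)
    theta_grid, cdf = _bend_angle_inverse_cdf(p.lp, p.b)
    n_bends = p.n_nodes - 2
    u_theta = _ar1_uniforms(rng, (p.n_frames, n_bends), p.rho)
    theta = np.interp(u_theta, cdf, theta_grid)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=(p.n_frames, n_bends))

    t = np.zeros((p.n_frames, p.n_nodes - 1, 3))
    t[:, 0, 2] = 1.0
    cur = t[:, 0, :].copy()
    for j in range(n_bends):
        # orthonormal frame perpendicular to the current tangent
        helper = np.where(
            np.abs(cur[:, 2:3]) < 0.9,
            np.array([0.0, 0.0, 1.0]),
            np.array([1.0, 0.0, 0.0]),
        )
        u = np.cross(cur, helper)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(cur, u)
        ct, st = np.cos(theta[:, j]), np.sin(theta[:, j])
        cp, sp = np.cos(psi[:, j]), np.sin(psi[:, j])
        cur = (
            ct[:, None] * cur
            + st[:, None] * (cp[:, None] * u + sp[:, None] * v)
        )
        cur /= np.linalg.norm(cur, axis=1, keepdims=True)
        t[:, j + 1, :] = cur

    nodes = np.zeros((p.n_frames, p.n_nodes, 3))
    nodes[:, 1:, :] = np.cumsum(p.b * t, axis=1)
    return Trajectory([ChainTrace(frame) for frame in nodes])


# ---------------------------------------------------------------------------
# Helical lattice ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixEnsembleParams:
    """Point-subunit helix ensemble: rise/twist lattice + thermal noise."""

    n_subunits: int = 13
    rise: float = 27.5          # Å/subunit
    twist: float = -166.15      # deg/subunit, negative = left-handed
    radius: float = 25.0        # Å, subunit COG radius from the axis
    sigma_xyz: float = 0.0      # Å, iid Gaussian displacement per coordinate
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("n_subunits must be >= 3")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sigma_xyz < 0:
            raise ValueError("sigma_xyz must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def ideal_helix_points(
    n_subunits: int, rise: float, twist: float, radius: float
) -> np.ndarray:
    """Subunit positions of an ideal helix, shape (n, 3)."""
    i = np.arange(n_subunits)
    ang = np.deg2rad(twist) * i
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * i]
    )


def generate_helix_ensemble(p: HelixEnsembleParams) -> Trajectory:
    """Ideal helix plus iid Gaussian positional noise, per frame."""
    rng = np.random.default_rng(p.seed)
    ideal = ideal_helix_points(p.n_subunits, p.rise, p.twist, p.radius)
    frames = []
    for _ in range(p.n_frames):
        pts = ideal
        if p.sigma_xyz > 0:
            pts = ideal + rng.normal(0.0, p.sigma_xyz, size=ideal.shape)
        frames.append(
            FilamentModel.from_points(pts, axial_repeat=p.n_subunits * p.rise)
        )
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Diffraction peak profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSimParams:
    """Gaussian reflection(s) on a sloping background.

    ``second`` optionally adds a (centre, sigma, amplitude) component;
    overlapping a narrow and a broad component of different centres
    produces the asymmetric, window-sensitive composite characteristic
    of two co-existing filament populations.
    """

    n_pixels: int = 201
    centre: float = 100.0       # fractional pixel
    sigma: float = 5.0          # pixels
    amplitude: float = 1000.0
    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    second: tuple[float, float, float] | None = None  # (centre, sigma, amplitude)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.centre < self.n_pixels - 1:
            raise ValueError("centre must lie inside the pixel axis")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.second is not None and self.second[1] <= 0:
            raise ValueError("second-component sigma must be positive")


def generate_peak_profile(
    p: PeakSimParams, calibration: Calibration | None = None
) -> IntensityProfile:
    """Evaluate the peak model on an integer pixel axis, with noise."""
    x = np.arange(p.n_pixels, dtype=float)
    y = p.intercept + p.slope * x
    y = y + p.amplitude * np.exp(-((x - p.centre) ** 2) / (2.0 * p.sigma**2))
    if p.second is not None:
        mu2, s2, a2 = p.second
        y = y + a2 * np.exp(-((x - mu2) ** 2) / (2.0 * s2**2))
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        y = y + rng.normal(0.0, p.noise_sd, size=x.shape)
    return IntensityProfile(x, y, calibration)


# ---------------------------------------------------------------------------
# Speed mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedSimParams:
    """Gaussian speed mixture, truncated at zero by redraw."""

    weights: tuple[float, ...]
    means: tuple[float, ...]      # μm/s
    sds: tuple[float, ...]        # μm/s
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        k = len(self.weights)
        if len(self.means) != k or len(self.sds) != k:
            raise ValueError("weights, means and sds must share one length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")


def generate_speed_sample(
    p: SpeedSimParams, label: str | None = None
) -> SpeedSample:
    """Draw n speeds from the mixture; negatives are redrawn, not clipped."""
    rng = np.random.default_rng(p.seed)
    comp = rng.choice(len(p.weights), size=p.n, p=np.asarray(p.weights))
    means = np.asarray(p.means)[comp]
    sds = np.asarray(p.sds)[comp]
    speeds = rng.normal(means, sds)
    bad = speeds < 0
    while np.any(bad):
        speeds[bad] = rng.normal(means[bad], sds[bad])
        bad = speeds < 0
    return SpeedSample(speeds, label=label)


# ---------------------------------------------------------------------------
# Full-residue synthetic filaments (for the contact / CG geometry stage)
# ---------------------------------------------------------------------------

def synthetic_subunit(
    seed: int = 0,
    n_residues: int = 375,
    centre=(25.0, 0.0, 0.0),
    radius: float = 27.0,
):
    """A synthetic single-Cα-per-residue subunit coordinate table.

    Residues are placed inside a sphere of the given radius about
    ``centre`` (off-axis, so a filament built from it has a realistic
    subunit-COG radius; the default 27 Å matches the ~55 Å span of an
    actin monomer).  Two regions are positioned rather than random, so
    the filament reproduces the geometry the contact analysis assumes:
    the D-loop (residues 38-52) sits on the +z face, pointing up the
    long-pitch strand, and the regions it contacts on the subunit above
    (130-150, 161-175, 345-357, 369-375) sit on the -z face.  Everything
    else is a geometric stand-in: no secondary structure, no chemistry.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_residues, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.uniform(0.0, 1.0, size=(n_residues, 1)) ** (1.0 / 3.0)

    def place_cap(residues, pole, spread=0.35):
        for r in residues:
            if r > n_residues:
                continue
            direction = pole + rng.normal(0.0, spread, 3)
            direction /= np.linalg.norm(direction)
            pts[r - 1] = direction * radius * rng.uniform(0.92, 1.0)

    up, down = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])
    place_cap(range(38, 53), up)
    for lo, hi in ((130, 150), (161, 175), (345, 357), (369, 375)):
        place_cap(range(lo, hi + 1), down)
    pts += np.asarray(centre, dtype=float)
    return {i + 1: {"CA": pts[i]} for i in range(n_residues)}


def generate_filament_ensemble(
    subunit,
    n_subunits: int = 13,
    rise: float = 27.5,
    twist: float = -166.15,
    sigma_xyz: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
) -> Trajectory:
    """Ideal filament from one subunit, plus per-atom Gaussian noise."""
    ideal = build_ideal_filament(subunit, n_subunits, rise, twist)
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        subs = []
        for sub in ideal.subunits:
            subs.append(
                {
                    r: {
                        a: xyz + rng.normal(0.0, sigma_xyz, 3)
                        if sigma_xyz > 0
                        else xyz.copy()
                        for a, xyz in atoms.items()
                    }
                    for r, atoms in sub.items()
                }
            )
        frames.append(FilamentModel(subs, axial_repeat=ideal.axial_repeat))
    return Trajectory(frames)
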