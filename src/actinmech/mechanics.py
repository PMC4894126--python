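"""Filament mechanical observables from conformational ensembles.

Three quantities characterise filament mechanics here:

* the persistence length ``Lp``, the decay length of the tangent-tangent
  correlation ``<t_i . t_{i+k}> = exp(-k b / Lp)`` along a discrete
  worm-like chain with segment length ``b``;
* the helical rise ``h`` (Å/subunit) and signed twist ``phi``
  (deg/subunit) of the genetic helix, estimated frame by frame from
  subunit centres of geometry;
* the crossover length ``L_c = 180 h / (180 - |phi|)``, the axial
  half-period over which the two long-pitch strands of F-actin cross.

Uncertainties of ensemble averages use Flyvbjerg-Petersen block
averaging, which remains valid for autocorrelated frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ANGSTROM_PER_MICROMETRE,
    ChainTrace,
    DegenerateGeometryError,
    FilamentModel,
    ResidueGroupSpec,
    Trajectory,
    cog,
)

__all__ = [
    "BlockAverageResult",
    "block_average",
    "blocked_means",
    "tangent_correlation",
    "PersistenceLengthModel",
    "PersistenceLengthResults",
    "estimate_persistence_length",
    "HelicalSymmetryModel",
    "HelicalParametersResults",
    "estimate_helical_parameters",
    "crossover_length",
]


# ---------------------------------------------------------------------------
# Block averaging (Flyvbjerg & Petersen style successive pairwise blocking)
# ---------------------------------------------------------------------------

@dataclass
class BlockAverageResult:
    """Standard error of a (possibly autocorrelated) series mean.

    ``se[l]`` is the SE estimate using blocks of ``block_sizes[l]``
    consecutive samples; for correlated data it grows with block size
    until the blocks are effectively independent and the curve plateaus.
    """

    block_sizes: np.ndarray
    se: np.ndarray
    plateau_se: float
    plateau_block_size: int
    plateau_level: int
    converged: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"block_size": self.block_sizes, "se": self.se})


def block_average(series, rel_tol: float = 0.05) -> BlockAverageResult:
    """Estimate the SE of a series mean by successive pairwise blocking.

    At level ``l`` the series is the means of ``2**l``-sample blocks and
    ``SE_l = sqrt(var_l / (n_l - 1))`` (population variance).  The plateau
    is the first level whose SE changed by less than ``rel_tol``
    relative to the previous level; if none is found the last level is
    used and the result is flagged unconverged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < 8:
        raise ValueError("block averaging needs at least 8 samples")
    sizes, ses = [], []
    level_x = x
    size = 1
    while len(level_x) >= 2:
        n_l = len(level_x)
        ses.append(float(np.sqrt(np.var(level_x) / (n_l - 1))))
        sizes.append(size)
        m = n_l // 2
        level_x = 0.5 * (level_x[: 2 * m : 2] + level_x[1 : 2 * m : 2])
        size *= 2
    sizes = np.asarray(sizes)
    ses = np.asarray(ses)
    plateau_level = None
    for lvl in range(1, len(ses)):
        prev = ses[lvl - 1]
        if prev == 0.0 or abs(ses[lvl] - prev) < rel_tol * prev:
            plateau_level = lvl
            break
    converged = plateau_level is not None
    if plateau_level is None:
        plateau_level = len(ses) - 1
    return BlockAverageResult(
        block_sizes=sizes,
        se=ses,
        plateau_se=float(ses[plateau_level]),
        plateau_block_size=int(sizes[plateau_level]),
        plateau_level=int(plateau_level),
        converged=converged,
    )


def blocked_means(series, block_size: int) -> np.ndarray:
    """Means of consecutive non-overlapping blocks (tail dropped)."""
    x = np.asarray(series, dtype=float)
    n_blocks = len(x) // block_size
    if n_blocks < 1:
        raise ValueError("block_size exceeds series length")
    return x[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)


# ---------------------------------------------------------------------------
# Tangent correlations and persistence length
# ---------------------------------------------------------------------------

def _frame_correlations(traj: Trajectory, k_max: int) -> np.ndarray:
    """Per-frame mean tangent correlation, shape (F, k_max + 1).

    Computed for all separations at once through FFT autocorrelation of
    the unit-tangent series of each frame.
    """
    nodes = traj.node_array()
    d = np.diff(nodes, axis=1)
    t = d / np.linalg.norm(d, axis=2, keepdims=True)
    n_t = t.shape[1]
    if not (1 <= k_max <= n_t - 1):
        raise ValueError(
            f"k_max must be in 1..{n_t - 1} (n_nodes - 2) for this trajectory"
        )
    size = 1 << int(np.ceil(np.log2(2 * n_t)))
    spec = np.fft.rfft(t, n=size, axis=1)
    acf = np.fft.irfft((spec * spec.conj()).real.sum(axis=2), n=size, axis=1)
    acf = acf[:, : k_max + 1]
    counts = n_t - np.arange(k_max + 1)
    return acf / counts


def tangent_correlation(traj: Trajectory, k_max: int) -> pd.DataFrame:
    """Average tangent-tangent correlation ``<cos theta_k>`` vs separation.

    The average runs over all frames and all tangent pairs separated by
    ``k`` segments.  For a worm-like chain the expectation is
    ``exp(-k b / Lp)``.

    Returns a DataFrame with columns ``k`` (1..k_max) and ``mean_cos``.
    """
    per_frame = _frame_correlations(traj, k_max)
    mean = per_frame.mean(axis=0)
    return pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "mean_cos": mean[1:]}
    )


@dataclass
class PersistenceLengthResults:
    """Persistence length estimate from tangent-correlation decay."""

    lp_um: float
    sd_um: float
    fit_range: int          # largest tangent separation (segments) in the fit
    n_frames_used: int
    slope: float            # slope of ln<cos theta_k> vs k
    segment_length: float   # b, Å
    correlations: pd.DataFrame
    block_result: BlockAverageResult | None
    beyond_resolvable: bool

    @property
    def lp_angstrom(self) -> float:
        return self.lp_um * ANGSTROM_PER_MICROMETRE

    def summary(self) -> str:
        lines = [
            "Persistence length (tangent-correlation fit)",
            "-" * 46,
            f"Lp                {self.lp_um:12.4g} um",
            f"sd (block avg)    {self.sd_um:12.4g} um",
            f"fit range k*      {self.fit_range:12d} segments",
            f"segment length b  {self.segment_length:12.4g} A",
            f"frames used       {self.n_frames_used:12d}",
        ]
        if self.beyond_resolvable:
            lines.append("flag: decay beyond resolvable (chain effectively rigid)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """ln <cos theta_k> vs k with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = self.correlations["k"].to_numpy()
        c = self.correlations["mean_cos"].to_numpy()
        ok = c > 0
        ax.plot(k[ok], np.log(c[ok]), ".", label="data")
        kk = k[k <= self.fit_range]
        ax.plot(kk, self.slope * kk, "-", label="fit")
        ax.set_xlabel("separation k (segments)")
        ax.set_ylabel(r"$\ln\langle\cos\theta_k\rangle$")
        ax.legend()
        return ax


class PersistenceLengthModel:
    """Persistence length of a filament trace ensemble.

    The estimator fits ``ln <cos theta_k>`` against ``k`` over
    ``k = 1..k*`` and reports ``Lp = -b / slope``.  By default ``k*`` is
    the largest separation at which the mean correlation still exceeds
    ``min_corr`` (0.9); at least two separations are always used.
    Confining the fit to the initial decay is deliberate: at large
    separations the log-correlation estimate is dominated by a few
    long-wavelength bending modes, so its errors are large and strongly
    correlated across ``k``, and including them inflates the slope
    variance several-fold.

    The quoted uncertainty is the standard deviation of per-frame
    estimates blocked at the block-averaging plateau, so it remains
    meaningful for autocorrelated trajectories.
    """

    def __init__(self, traj: Trajectory):
        if not isinstance(traj.frames[0], ChainTrace):
            raise TypeError("PersistenceLengthModel requires ChainTrace frames")
        self.traj = traj

    def fit(
        self,
        k_max: int | None = None,
        k_star: int | None = None,
        min_corr: float = 0.9,
    ) -> PersistenceLengthResults:
        traj = self.traj
        n_nodes = traj.frames[0].n_nodes
        if k_max is None:
            k_max = n_nodes - 2
        per_frame = _frame_correlations(traj, k_max)
        mean = per_frame.mean(axis=0)[1:]  # k = 1..k_max
        table = pd.DataFrame(
            {"k": np.arange(1, k_max + 1), "mean_cos": mean}
        )
        if k_star is None:
            above = np.nonzero(mean <= min_corr)[0]
            k_star = int(above[0]) if len(above) else k_max
            k_star = max(k_star, 2)
        k_star = min(k_star, k_max)
        fit_c = mean[:k_star]
        if np.any(fit_c <= 0):
            raise ValueError(
                "non-positive tangent correlations inside the fit range; "
                "re-fit with a smaller k_star"
            )
        ks = np.arange(1, k_star + 1)
        slope = float(np.polyfit(ks, np.log(fit_c), 1)[0])
        b = float(np.mean([f.b for f in traj.frames]))
        beyond = slope >= -1e-12
        lp_um = (
            np.inf if beyond else -b / slope / ANGSTROM_PER_MICROMETRE
        )

        lp_frames = self._per_frame_estimates(per_frame, k_star, b)
        valid = lp_frames[np.isfinite(lp_frames)]
        block = None
        sd_um = float("nan")
        if len(valid) >= 8:
            block = block_average(valid)
            bm = blocked_means(valid, block.plateau_block_size)
            sd_um = float(np.std(bm, ddof=1)) if len(bm) > 1 else 0.0
        elif len(valid) > 1:
            sd_um = float(np.std(valid, ddof=1))
        return PersistenceLengthResults(
            lp_um=float(lp_um),
            sd_um=sd_um,
            fit_range=int(k_star),
            n_frames_used=traj.n_frames,
            slope=slope,
            segment_length=b,
            correlations=table,
            block_result=block,
            beyond_resolvable=bool(beyond),
        )

    @staticmethod
    def _per_frame_estimates(per_frame, k_star, b) -> np.ndarray:
        """Per-frame Lp (μm); NaN where a frame's decay is unresolvable."""
        out = np.full(per_frame.shape[0], np.nan)
        ks_full = np.arange(1, k_star + 1)
        for fi, row in enumerate(per_frame[:, 1 : k_star + 1]):
            nonpos = np.nonzero(row <= 0)[0]
            stop = nonpos[0] if len(nonpos) else k_star
            if stop < 2:
                continue
            slope = np.polyfit(ks_full[:stop], np.log(row[:stop]), 1)[0]
            if slope < -1e-30:
                out[fi] = -b / slope / ANGSTROM_PER_MICROMETRE
        return out


def estimate_persistence_length(
    traj: Trajectory, **fit_kwargs
) -> PersistenceLengthResults:
    """Functional wrapper around :class:`PersistenceLengthModel`."""
    return PersistenceLengthModel(traj).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# Helical symmetry
# ---------------------------------------------------------------------------

def crossover_length(rise: float, twist: float) -> float:
    """Crossover length ``L_c = 180 h / (180 - |phi|)`` in Å.

    ``L_c`` is the axial half-period of the two-start (long-pitch) helix:
    the genetic helix advances by ``180 - |phi|`` degrees of long-pitch
    phase per subunit, so the strands cross every ``180 / (180 - |phi|)``
    subunits.  For F-actin (h ≈ 27.5 Å, phi ≈ -166.6°) this is ~370 Å.
    """
    if rise <= 0:
        raise ValueError("rise must be positive")
    a = abs(twist)
    if not 0 < a < 180:
        raise ValueError("|twist| must lie strictly between 0 and 180 degrees")
    return 180.0 * rise / (180.0 - a)


def _helix_axis(points: np.ndarray) -> np.ndarray:
    """Unit axis direction of a (noisy) helical point sequence.

    For four or more points the axis is the normal of the least-squares
    plane through the second differences ``p_{i+2} - 2 p_{i+1} + p_i``,
    which are exactly perpendicular to the axis for an ideal helix (the
    axial part of ``p_i`` is linear in ``i``).  Three points fall back to
    the principal axis of the point cloud.
    """
    n = len(points)
    if n >= 4:
        s = points[2:] - 2.0 * points[1:-1] + points[:-2]
        m = s.T @ s
        w, v = np.linalg.eigh(m)
        axis = v[:, 0]
    else:
        centred = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _frame_helix(points: np.ndarray) -> tuple[float, float]:
    """(rise, signed twist) of one frame's subunit-COG sequence."""
    axis = _helix_axis(points)
    proj = points @ axis
    rise = float(np.mean(np.diff(proj)))
    if rise <= 0:
        raise DegenerateGeometryError("non-positive axial rise along the axis")
    # Perpendicular parts of consecutive difference vectors rotate by
    # exactly the twist per subunit and are independent of where the axis
    # sits, so no axis-centre estimate is needed.
    diffs = np.diff(points, axis=0)
    perp = diffs - np.outer(diffs @ axis, axis)
    norms = np.linalg.norm(perp, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError(
            "subunits lie on the helix axis; twist undefined at zero radius"
        )
    a, bvec = perp[:-1], perp[1:]
    sin_part = np.cross(a, bvec) @ axis
    cos_part = np.einsum("ij,ij->i", a, bvec)
    increments = np.degrees(np.arctan2(sin_part, cos_part))
    twist = float(np.mean(increments))
    return rise, twist


@dataclass
class HelicalParametersResults:
    """Helical rise, twist and crossover length of a filament ensemble.

    Means are over frames; ``*_sd`` are standard deviations over frames
    (0 for a single frame) and ``*_block`` hold the block-averaging
    diagnostics of each per-frame series when enough frames exist.
    """

    rise: float
    twist: float
    crossover: float
    rise_sd: float
    twist_sd: float
    crossover_sd: float
    n_frames: int
    per_frame: pd.DataFrame
    rise_block: BlockAverageResult | None = None
    twist_block: BlockAverageResult | None = None
    crossover_block: BlockAverageResult | None = None

    def summary(self) -> str:
        return "\n".join(
            [
                "Helical symmetry (per-frame axis fit)",
                "-" * 46,
                f"rise h          {self.rise:12.4f} +/- {self.rise_sd:.4f} A/subunit",
                f"twist phi       {self.twist:12.4f} +/- {self.twist_sd:.4f} deg/subunit",
                f"crossover L_c   {self.crossover:12.4f} +/- {self.crossover_sd:.4f} A",
                f"frames          {self.n_frames:12d}",
            ]
        )


class HelicalSymmetryModel:
    """Estimate rise/twist/crossover from a filament trajectory.

    Per frame, the helix axis is fitted (see :func:`_helix_axis`), the
    rise is the mean axial spacing of consecutive subunit COGs and the
    twist is the mean signed azimuthal increment about the axis
    (negative = left-handed).  Ensemble means and SDs are taken over
    frames.
    """

    def __init__(self, traj: Trajectory):
        if not isinstance(traj.frames[0], FilamentModel):
            raise TypeError("HelicalSymmetryModel requires FilamentModel frames")
        if traj.frames[0].n_subunits < 3:
            raise ValueError("need at least 3 subunits per frame")
        self.traj = traj

    def fit(
        self,
        group: ResidueGroupSpec | None = None,
        representation: str = "heavy",
    ) -> HelicalParametersResults:
        rows = []
        for frame in self.traj.frames:
            pts = np.vstack(
                [
                    cog(frame, i, group, representation)
                    for i in range(frame.n_subunits)
                ]
            )
            h, phi = _frame_helix(pts)
            rows.append((h, phi, crossover_length(h, phi)))
        per_frame = pd.DataFrame(rows, columns=["rise", "twist", "crossover"])
        n = len(per_frame)

        def sd(col):
            return float(per_frame[col].std(ddof=1)) if n > 1 else 0.0

        blocks = {}
        for col in per_frame.columns:
            blocks[col] = (
                block_average(per_frame[col].to_numpy()) if n >= 8 else None
            )
        return HelicalParametersResults(
            rise=float(per_frame["rise"].mean()),
            twist=float(per_frame["twist"].mean()),
            crossover=float(per_frame["crossover"].mean()),
            rise_sd=sd("rise"),
            twist_sd=sd("twist"),
            crossover_sd=sd("crossover"),
            n_frames=n,
            per_frame=per_frame,
            rise_block=blocks["rise"],
            twist_block=blocks["twist"],
            crossover_block=blocks["crossover"],
        )


def estimate_helical_parameters(
    traj: Trajectory, **fit_kwargs
) -> HelicalParametersResults:
    """Functional wrapper around :class:`HelicalSymmetryModel`."""
    return HelicalSymmetryModel(traj).fit(**fit_kwargs)
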