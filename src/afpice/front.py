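"""Occupancy-averaged ice-front extraction and curvature analysis.

The time-averaged ice front is defined through a water-occupancy map: the
box is voxelised (default 1 A) and each voxel records the fraction of
frames in which it is covered by a water oxygen, oxygens being rasterised
as spheres of 1.4 A radius.  Waters that belong to the ice phase sit at
persistent sites and produce voxels with occupancy near 1, while diffusing
liquid waters smear their density over many voxels, so thresholding the
map (default 85% occupancy) isolates the ice.  The front surface is the
top of the thresholded region in each (x, y) column, required to be
connected to the seed: short vertical gaps (default up to 3 voxels, the
size of the open channels of the ice-Ih lattice) are tolerated, anything
longer terminates the column.

For a front pinned by adsorbed AFPs at periodic sites the equilibrated
shape between pins is cylindrical; a least-squares circle fit to the y-z
profile (averaged over x, the cylinder axis) measures its radius for
comparison with the Gibbs-Thomson critical radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .thermo import WaterModelParams, critical_radius
from .traj import Trajectory, OXYGEN_ROLES

__all__ = [
    "OccupancyGrid",
    "FrontSurface",
    "CylinderFit",
    "GibbsThomsonComparison",
    "occupancy_map",
    "extract_front",
    "fit_cylinder",
    "compare_gibbs_thomson",
]


@dataclass
class OccupancyGrid:
    """Voxelised per-frame water-coverage fractions in [0, 1]."""

    occupancy: np.ndarray
    voxel: float
    box: np.ndarray
    n_frames: int

    def centers(self, axis: int) -> np.ndarray:
        return (np.arange(self.occupancy.shape[axis]) + 0.5) * self.voxel


def occupancy_map(
    traj: Trajectory,
    t_start: float | None = None,
    t_end: float | None = None,
    voxel: float = 1.0,
    radius: float = 1.4,
    roles=OXYGEN_ROLES,
) -> OccupancyGrid:
    """Per-voxel fraction of frames covered by any water oxygen.

    A voxel counts as covered in a frame when its centre lies within
    ``radius`` of an oxygen of one of the requested roles (periodic in x
    and y).  A window of at least 100 frames is recommended for an 85%
    threshold to be meaningful; shorter windows trigger a warning.
    """
    times = traj.times
    mask = np.ones(traj.n_frames, dtype=bool)
    if t_start is not None:
        mask &= times >= t_start
    if t_end is not None:
        mask &= times <= t_end
    frames = np.nonzero(mask)[0]
    if len(frames) == 0:
        raise ValueError("zero-length averaging window")
    if len(frames) < 100:
        warnings.warn(
            f"averaging over only {len(frames)} frames; occupancy thresholds "
            "near 1 are noisy below ~100 frames",
            stacklevel=2,
        )
    box = np.asarray(traj.box, float)
    shape = np.maximum(np.round(box / voxel).astype(int), 1)
    idx_atoms = traj.atoms_with_role(*roles)

    # stencil of voxel-centre offsets that can lie within `radius` of a point
    # anywhere inside the central voxel
    reach = int(np.ceil(radius / voxel + 0.5))
    rng = np.arange(-reach, reach + 1)
    offsets = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(offsets, axis=1) * voxel <= radius + voxel * np.sqrt(3.0) / 2.0
    offsets = offsets[keep]

    counts = np.zeros(shape, dtype=np.int32)
    nx, ny, nz = shape
    for f in frames:
        pos = traj.coords[f, idx_atoms, :]
        base = np.floor(pos / voxel).astype(int)
        cand = base[:, None, :] + offsets[None, :, :]
        centers = (cand + 0.5) * voxel
        d = centers - pos[:, None, :]
        # periodic x, y: candidates were generated un-wrapped so distances
        # are already minimal; wrap the voxel index instead
        within = np.linalg.norm(d, axis=-1) <= radius
        vox = cand[within]
        vox[:, 0] %= nx
        vox[:, 1] %= ny
        inz = (vox[:, 2] >= 0) & (vox[:, 2] < nz)
        vox = vox[inz]
        flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
        hit = np.zeros(int(np.prod(shape)), dtype=bool)
        hit[flat] = True
        counts += hit.reshape(shape)
    return OccupancyGrid(
        occupancy=counts / len(frames), voxel=voxel, box=box, n_frames=len(frames)
    )


@dataclass
class FrontSurface:
    """Occupancy-thresholded ice-front height field z(x, y)."""

    heights: np.ndarray
    x: np.ndarray
    y: np.ndarray
    threshold: float
    interpolated: np.ndarray


def extract_front(
    grid: OccupancyGrid,
    threshold: float = 0.85,
    seed_top_z: float = 0.0,
    max_gap: int = 3,
    smooth: float | None = None,
) -> FrontSurface:
    """Height of the ice phase in every (x, y) column of the occupancy map.

    Starting just above ``seed_top_z``, each column is scanned upward
    through the thresholded occupancy; the front height is the top of the
    last above-threshold voxel reachable without crossing a vertical gap
    longer than ``max_gap`` voxels.  Columns with no above-threshold voxel
    near the seed are filled by linear interpolation along y and flagged.
    ``smooth``, if given, applies a Gaussian kernel of that width (A) to
    the final height field.
    """
    occ = grid.occupancy
    nx, ny, nz = occ.shape
    zc = grid.centers(2)
    k0 = int(np.searchsorted(zc, seed_top_z))
    if k0 >= nz:
        raise ValueError("seed_top_z above the occupancy grid")
    solid = occ >= threshold
    if not solid[:, :, k0:].any():
        raise ValueError(f"no voxel above occupancy {threshold} anywhere above the seed")
    heights = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            col = solid[i, j, k0:]
            hits = np.nonzero(col)[0]
            if len(hits) == 0 or hits[0] > max_gap:
                continue
            gaps = np.diff(hits)
            stop = np.nonzero(gaps > max_gap + 1)[0]
            top = hits[stop[0]] if len(stop) else hits[-1]
            heights[i, j] = zc[k0 + top] + grid.voxel / 2.0

    interpolated = np.isnan(heights)
    for i in range(nx):
        row = heights[i]
        bad = np.isnan(row)
        if bad.all():
            continue
        if bad.any():
            idx = np.arange(ny)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad], period=ny)
        heights[i] = row
    if np.isnan(heights).any():
        # entire x-rows missing: fall back to the column-wise mean surface
        col_mean = np.nanmean(heights, axis=0)
        for i in range(nx):
            if np.isnan(heights[i]).all():
                heights[i] = col_mean
    if smooth is not None:
        from scipy.ndimage import gaussian_filter

        heights = gaussian_filter(heights, sigma=smooth / grid.voxel, mode="wrap")
    return FrontSurface(
        heights=heights,
        x=grid.centers(0),
        y=grid.centers(1),
        threshold=threshold,
        interpolated=interpolated,
    )


@dataclass
class CylinderFit:
    """Least-squares circle fit to the x-averaged y-z front profile."""

    radius: float
    center: tuple[float, float]
    rms_residual: float
    convex: bool | None
    finite: bool

    def __post_init__(self) -> None:
        if self.finite and not self.radius > 0:
            raise ValueError("fitted radius must be positive")


def fit_cylinder(
    front: FrontSurface,
    axis: str = "x",
    flat_radius_factor: float = 20.0,
) -> CylinderFit:
    """Fit a circle to the front profile perpendicular to the cylinder axis.

    The height field is averaged along ``axis`` (the AFP rows pin the
    front along x in the reference geometry) and a circle is fitted to
    the resulting profile by least squares (Kasa initialisation followed
    by geometric refinement).  A profile whose best-fit radius exceeds
    ``flat_radius_factor`` times its lateral span is reported as having
    no finite curvature (``finite=False``) rather than as a failure.
    ``convex`` is True when the surface bulges toward the liquid (circle
    centre below the profile).
    """
    if axis == "x":
        prof = np.nanmean(front.heights, axis=0)
        coord = front.y
    elif axis == "y":
        prof = np.nanmean(front.heights, axis=1)
        coord = front.x
    else:
        raise ValueError("axis must be 'x' or 'y'")
    ok = np.isfinite(prof)
    u, z = coord[ok], prof[ok]
    if len(u) < 3:
        raise ValueError("front profile too short for a circle fit")
    span = np.ptp(u)

    # Kasa algebraic fit: minimise ||(u-a)^2 + (z-b)^2 - R^2|| in linear form
    A = np.column_stack([2 * u, 2 * z, np.ones_like(u)])
    rhs = u**2 + z**2
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        a0, b0 = sol[0], sol[1]
        r0 = float(np.sqrt(max(sol[2] + a0**2 + b0**2, 1e-12)))
    except np.linalg.LinAlgError:  # pragma: no cover
        a0, b0, r0 = np.mean(u), np.mean(z), span

    if not np.isfinite(r0) or r0 > flat_radius_factor * span:
        rms = float(np.sqrt(np.mean((z - np.mean(z)) ** 2)))
        return CylinderFit(
            radius=np.inf, center=(float(np.mean(u)), float(np.mean(z))),
            rms_residual=rms, convex=None, finite=False,
        )

    def residuals(p):
        a, b, r = p
        return np.hypot(u - a, z - b) - r

    res = optimize.least_squares(residuals, x0=[a0, b0, r0])
    a, b, r = res.x
    rms = float(np.sqrt(np.mean(residuals(res.x) ** 2)))
    if r > flat_radius_factor * span:
        return CylinderFit(
            radius=np.inf, center=(float(a), float(b)), rms_residual=rms,
            convex=None, finite=False,
        )
    return CylinderFit(
        radius=float(abs(r)),
        center=(float(a), float(b)),
        rms_residual=rms,
        convex=bool(b < np.median(z)),
        finite=True,
    )


@dataclass
class GibbsThomsonComparison:
    """Measured front radius against the Gibbs-Thomson critical radius."""

    fitted_radius: float
    theoretical_radius: float
    ratio: float
    params_name: str
    supercooling: float


def compare_gibbs_thomson(
    fit: CylinderFit | float,
    params: WaterModelParams,
    supercooling: float,
) -> GibbsThomsonComparison:
    """Ratio of a fitted cylindrical front radius to Gibbs-Thomson theory.

    The comparison is dimensionless (both radii in A), so it is invariant
    under a common change of length units.
    """
    fitted = fit.radius if isinstance(fit, CylinderFit) else float(fit)
    if isinstance(fit, CylinderFit) and not fit.finite:
        raise ValueError("cylinder fit reported no finite curvature")
    theory = critical_radius(params, supercooling, geometry="cylindrical").R_angstrom
    return GibbsThomsonComparison(
        fitted_radius=fitted,
        theoretical_radius=theory,
        ratio=fitted / theory,
        params_name=params.name,
        supercooling=supercooling,
    )
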