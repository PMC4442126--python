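"""Water-mobility classification and ice-fraction statistics.

A water molecule is classified as immobile -- i.e. ice -- at frame ``t``
when its oxygen stays within a displacement threshold (default 0.8 A)
over a short window of successive frames (default 3 frames = 200 ps at
the 100 ps capture interval).  Two readings of "moved less than 0.8 A"
are provided: the default measures the maximum excursion of the oxygen
from its window-mean position, which is stable against single-frame
vibration; ``mode="endpoint"`` measures the first-to-last displacement
instead.  Windows overlap (they slide by one frame).

The ice fraction is the proportion of ice-labelled water molecules in a
region of interest, by default everything above the topmost constrained
seed oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traj import Trajectory

__all__ = [
    "PhaseLabels",
    "IceFractionSeries",
    "EquilibriumStats",
    "unwrap_coordinates",
    "classify_ice",
    "ice_fraction",
    "equilibrium_stats",
]

ICE, LIQUID = 1, 0


@dataclass
class PhaseLabels:
    """Per-water, per-frame phase labels.

    ``labels[t, k]`` is 1 (ice) or 0 (liquid) for window-start frame ``t``
    and water ``atom_indices[k]``; labels exist only for frames with a
    complete window, i.e. ``t < n_frames - window_frames + 1``.
    """

    labels: np.ndarray
    atom_indices: np.ndarray
    disp_threshold: float
    window_frames: int
    times: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.labels.shape[0]


def unwrap_coordinates(coords: np.ndarray, box: np.ndarray, periodic=(True, True, False)):
    """Remove periodic jumps from an (F, N, 3) coordinate block.

    Frame-to-frame displacements are minimum-imaged along the periodic
    axes and re-accumulated from the first frame.
    """
    disp = np.diff(coords, axis=0)
    box = np.asarray(box, float)
    for ax in range(3):
        if periodic[ax] and box[ax] > 0:
            disp[..., ax] -= box[ax] * np.rint(disp[..., ax] / box[ax])
    out = np.empty_like(coords)
    out[0] = coords[0]
    np.cumsum(disp, axis=0, out=disp)
    out[1:] = coords[0] + disp
    return out


def classify_ice(
    traj: Trajectory,
    disp_threshold: float = 0.8,
    window_frames: int = 3,
    mode: str = "mean",
) -> PhaseLabels:
    """Label every water oxygen ice/liquid by its short-time mobility.

    Parameters
    ----------
    disp_threshold : float
        Displacement threshold in A (must be positive).
    window_frames : int
        Number of successive frames per window.
    mode : {"mean", "endpoint"}
        "mean": ice iff the maximum deviation of the oxygen from its
        window-mean position stays below the threshold.  "endpoint": ice
        iff the first-to-last displacement does.
    """
    if disp_threshold <= 0:
        raise ValueError("disp_threshold must be positive")
    if window_frames < 2:
        raise ValueError("window_frames must be at least 2")
    if traj.n_frames < window_frames:
        raise ValueError(
            f"window of {window_frames} frames longer than trajectory ({traj.n_frames} frames)"
        )
    idx = traj.water_oxygens
    unwrapped = unwrap_coordinates(traj.coords[:, idx, :], traj.box)
    n_windows = traj.n_frames - window_frames + 1
    labels = np.empty((n_windows, len(idx)), dtype=np.int8)
    for t in range(n_windows):
        seg = unwrapped[t : t + window_frames]
        if mode == "mean":
            dev = np.linalg.norm(seg - seg.mean(axis=0), axis=-1).max(axis=0)
        elif mode == "endpoint":
            dev = np.linalg.norm(seg[-1] - seg[0], axis=-1)
        else:
            raise ValueError("mode must be 'mean' or 'endpoint'")
        labels[t] = np.where(dev < disp_threshold, ICE, LIQUID)
    return PhaseLabels(
        labels=labels,
        atom_indices=idx,
        disp_threshold=disp_threshold,
        window_frames=window_frames,
        times=traj.times[:n_windows],
    )


@dataclass
class IceFractionSeries:
    """Ice fraction over time within a z-region of the box."""

    times: np.ndarray
    fraction: np.ndarray
    region: tuple[float, float]

    def __post_init__(self) -> None:
        frac = self.fraction[np.isfinite(self.fraction)]
        if len(frac) and not ((frac >= 0) & (frac <= 1)).all():
            raise ValueError("ice fraction must lie in [0, 1]")


def ice_fraction(
    labels: PhaseLabels,
    traj: Trajectory,
    region: tuple[float, float] | None = None,
) -> IceFractionSeries:
    """Fraction of ice-labelled waters inside a z-region, per frame.

    ``region`` is a (z_min, z_max) slab; by default it spans from the
    topmost constrained seed oxygen to the top of the box ("above the ice
    seed crystal").  Region membership uses each water's position at the
    window-start frame.  Raises if the region never contains any water.
    """
    if region is None:
        region = (traj.seed_top_z(), float(traj.box[2]))
    z_min, z_max = region
    z = traj.coords[: labels.n_windows, labels.atom_indices, 2]
    in_region = (z > z_min) & (z <= z_max)
    n_in = in_region.sum(axis=1)
    if not n_in.any():
        raise ValueError(f"region {region} contains no water in any frame")
    with np.errstate(invalid="ignore"):
        frac = np.where(
            n_in > 0, (labels.labels.astype(bool) & in_region).sum(axis=1) / n_in, np.nan
        )
    return IceFractionSeries(times=labels.times, fraction=frac, region=(z_min, z_max))


@dataclass
class EquilibriumStats:
    """Mean, spread and drift of an ice-fraction window."""

    mean: float
    sd: float
    slope: float
    slope_ci: tuple[float, float]
    equilibrated: bool
    n_points: int


def equilibrium_stats(
    series: IceFractionSeries, t_start: float, t_end: float, ci_level: float = 0.95
) -> EquilibriumStats:
    """OLS drift statistics of the ice fraction over [t_start, t_end].

    The window is "equilibrated" when the confidence interval of the OLS
    slope covers zero (no appreciable growth or melting).
    """
    mask = (series.times >= t_start) & (series.times <= t_end) & np.isfinite(series.fraction)
    t = series.times[mask]
    f = series.fraction[mask]
    if len(t) < 10:
        raise ValueError(f"need at least 10 points in the window, got {len(t)}")
    res = stats.linregress(t, f)
    tval = stats.t.ppf(0.5 + ci_level / 2.0, len(t) - 2)
    ci = (res.slope - tval * res.stderr, res.slope + tval * res.stderr)
    return EquilibriumStats(
        mean=float(np.mean(f)),
        sd=float(np.std(f, ddof=1)),
        slope=float(res.slope),
        slope_ci=ci,
        equilibrated=bool(ci[0] <= 0.0 <= ci[1]),
        n_points=len(t),
    )
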