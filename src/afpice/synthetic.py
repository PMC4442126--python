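"""Synthetic trajectories and fixtures with known ground truth.

These generators emulate the statistical structure the trajectory
analyses rely on -- not the physics.  Ice-phase waters vibrate with a
small Gaussian amplitude about fixed ice-Ih lattice sites; liquid waters
perform uncorrelated Gaussian random walks above an advancing or pinned
front z_front(y, t); an AFP centre-of-mass track is diffusive and then
pinned at a fixed height.  Because every water's phase, the front height
field and the bind time are prescribed, each pipeline stage can be tested
against exact ground truth without running molecular dynamics.

Liquid motion here is non-interacting Brownian displacement, which is
sufficient for testing mobility classification, occupancy mapping and
front extraction but reproduces neither liquid structure nor dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeSpec, build_ice_lattice
from .traj import (
    ROLE_SEED,
    ROLE_WATER_O,
    Trajectory,
)

__all__ = [
    "GrowthScenario",
    "GroundTruth",
    "front_height",
    "generate_growth_trajectory",
    "generate_binding_track",
    "OrderedWaterFixture",
    "generate_ordered_water_fixture",
    "make_synthetic_afp",
    "write_synthetic_afp_pdb",
]


@dataclass(frozen=True)
class GrowthScenario:
    """Parameters of a synthetic ice-growth trajectory.

    ``front_model`` is one of ``flat`` (horizontal front at z0, optionally
    advancing), ``advance`` (front tilted by ``tilt_deg`` about x and
    advancing at ``velocity``) or ``pinned`` (static cylindrical arcs of
    ``radius`` between pinning sites spaced ``pin_spacing`` along y at
    height ``pin_z``).  Defaults mirror the analysis settings: 0.2 A ice
    vibration amplitude, 0.1 A^2/ps liquid diffusion, 100 ps frames.
    """

    box: tuple[float, float, float]
    n_frames: int
    front_model: str = "flat"
    z0: float = 10.0
    velocity: float = 0.0  # A/ns
    tilt_deg: float = 0.0
    pin_spacing: float | None = None
    pin_z: float | None = None
    radius: float | None = None
    amplitude: float = 0.2
    diffusion: float = 0.1  # A^2/ps
    dt_frame: float = 100.0
    seed: int = 0
    lattice: LatticeSpec = field(default_factory=LatticeSpec)

    def __post_init__(self) -> None:
        if self.front_model not in ("flat", "advance", "pinned"):
            raise ValueError(f"unknown front model {self.front_model!r}")
        if self.front_model == "pinned" and (
            self.pin_spacing is None or self.radius is None
        ):
            raise ValueError("pinned front needs pin_spacing and radius")
        if (
            self.front_model == "pinned"
            and self.radius < self.pin_spacing / 2.0
        ):
            raise ValueError("cylinder radius must be at least half the pin spacing")
        if self.amplitude >= 0.8 / 2.0:
            warnings.warn(
                f"ice vibration amplitude {self.amplitude} A approaches the 0.8 A "
                "classifier threshold; phases may not be separable",
                stacklevel=2,
            )
        step = math.sqrt(2.0 * self.diffusion * self.dt_frame)
        if step <= 0.8:
            warnings.warn(
                f"liquid diffusion step {step:.2f} A per frame is below the "
                "classifier threshold; phases may not be separable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for checking the analyses."""

    frozen: np.ndarray  # (F, N) bool phase labels
    front_y: np.ndarray  # y grid of the height field
    front_heights: np.ndarray  # (F, len(front_y))
    sites: np.ndarray  # (N, 3) lattice site of every water
    bind_time: float | None = None


def front_height(scn: GrowthScenario, y: np.ndarray, t_ps: float) -> np.ndarray:
    """Prescribed front height z_front(y, t) for a scenario."""
    y = np.asarray(y, float)
    advance = scn.velocity * t_ps / 1000.0
    if scn.front_model in ("flat", "advance"):
        slope = math.tan(math.radians(scn.tilt_deg)) if scn.front_model == "advance" else 0.0
        z = scn.z0 + slope * y + advance
    else:
        s = scn.pin_spacing
        pin_z = scn.pin_z if scn.pin_z is not None else scn.z0
        r = scn.radius
        y_local = np.mod(y, s) - s / 2.0
        sag = math.sqrt(r**2 - (s / 2.0) ** 2)
        z = pin_z - sag + np.sqrt(np.maximum(r**2 - y_local**2, 0.0)) + advance
    zmax = scn.box[2] - 1.0
    if np.any(z > zmax):
        warnings.warn("front exits the box; truncating at the top", stacklevel=2)
        z = np.minimum(z, zmax)
    return np.maximum(z, 0.5)


def _slab_sites(scn: GrowthScenario, z_max: float) -> np.ndarray:
    """Ice-Ih lattice sites filling the box footprint up to z_max.

    Sites come from the builder lattice (a-axis along x, c-axis along y,
    prism layers stacked along z) so that synthetic ice shares its
    geometry with built seed slabs.
    """
    a, c = scn.lattice.a, scn.lattice.c
    bx, by, bz = scn.box
    spec = LatticeSpec(
        a=a,
        c=c,
        n_a=max(1, int(math.ceil(bx / a))),
        n_b=max(1, int(math.ceil(z_max / (math.sqrt(3.0) * a)))),
        n_c=max(1, int(math.ceil(by / c))),
        proton_seed=scn.lattice.proton_seed,
    )
    block = build_ice_lattice(spec)
    sites = block.oxygens[:, [0, 2, 1]]  # crystal frame -> slab frame
    keep = (
        (sites[:, 0] < bx - 0.05)
        & (sites[:, 1] < by - 0.05)
        & (sites[:, 2] < min(z_max, bz - 0.5))
    )
    return sites[keep]


def generate_growth_trajectory(scn: GrowthScenario) -> tuple[Trajectory, GroundTruth]:
    """Synthetic trajectory of vibrating ice plus diffusing liquid.

    Every water is tied to an ice-Ih lattice site.  While the front
    z_front(y, t) is above a water's site the water diffuses freely above
    the front; once the front passes its site the water freezes onto the
    site and only vibrates.  Waters frozen in the first frame are given
    the constrained-seed role so that region selections ("above the ice
    seed") work as on real trajectories.
    """
    rng = np.random.default_rng(scn.seed)
    F = scn.n_frames
    times = np.arange(F) * scn.dt_frame
    z_final = float(
        np.max(front_height(scn, np.linspace(0, scn.box[1], 64), times[-1]))
    )
    sites = _slab_sites(scn, min(scn.box[2] - 1.0, max(z_final + 6.0, scn.z0 + 6.0)))
    n = len(sites)

    frozen = np.empty((F, n), dtype=bool)
    for f in range(F):
        frozen[f] = sites[:, 2] < front_height(scn, sites[:, 1], times[f])

    coords = np.empty((F, n, 3))
    # ice: Gaussian vibration about the site
    vib = rng.normal(scale=scn.amplitude, size=(F, n, 3))
    step_sd = math.sqrt(2.0 * scn.diffusion * scn.dt_frame)
    walker = sites.copy()
    # lift initially liquid walkers above the initial front
    f0 = front_height(scn, walker[:, 1], 0.0)
    liquid0 = ~frozen[0]
    lift = liquid0 & (walker[:, 2] < f0 + 0.5)
    walker[lift, 2] = f0[lift] + 0.5 + rng.uniform(
        0.0, max(scn.box[2] - 2.0 - np.max(f0), 1.0), size=int(lift.sum())
    )
    for f in range(F):
        if f > 0:
            move = ~frozen[f - 1]
            walker[move] += rng.normal(scale=step_sd, size=(int(move.sum()), 3))
            walker[:, 0] %= scn.box[0]
            walker[:, 1] %= scn.box[1]
            zlo = front_height(scn, walker[:, 1], times[f]) + 0.2
            zhi = scn.box[2] - 0.2
            z = walker[:, 2]
            z = np.where(z > zhi, 2 * zhi - z, z)
            z = np.where(z < zlo, 2 * zlo - z, z)
            walker[:, 2] = np.clip(z, 0.0, scn.box[2])
        coords[f] = np.where(frozen[f][:, None], sites + vib[f], walker)

    roles = np.where(frozen[0], ROLE_SEED, ROLE_WATER_O).astype("<U4")
    y_grid = np.linspace(0.0, scn.box[1], 128, endpoint=False)
    front_heights = np.stack([front_height(scn, y_grid, t) for t in times])
    traj = Trajectory(
        coords=coords,
        box=np.asarray(scn.box, float),
        dt_frame=scn.dt_frame,
        roles=roles,
        times=times,
        meta={"scenario": scn},
    )
    truth = GroundTruth(
        frozen=frozen, front_y=y_grid, front_heights=front_heights, sites=sites
    )
    return traj, truth


def generate_binding_track(
    bind_time_ns: float | None,
    pin_z: float,
    n_frames: int,
    dt_frame: float = 100.0,
    diffusion: float = 0.05,
    jitter: float = 0.3,
    z_start: float | None = None,
    z_bounds: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """1-D AFP centre-of-mass height track: diffusive, then pinned.

    Returns ``(times, com_z, truth)``.  With ``bind_time_ns=None`` the
    track never binds (the ice-binding-surface mutant scenario).  Before
    binding the track is a reflected random walk within ``z_bounds``
    (default: 2 to 52 A above the pin height); from ``bind_time_ns`` on it
    sits at ``pin_z`` with Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt_frame
    lo, hi = z_bounds if z_bounds is not None else (pin_z + 2.0, pin_z + 52.0)
    z = np.empty(n_frames)
    z[0] = z_start if z_start is not None else 0.5 * (lo + hi)
    step_sd = math.sqrt(2.0 * diffusion * dt_frame)
    bind_frame = (
        None if bind_time_ns is None else int(round(bind_time_ns * 1000.0 / dt_frame))
    )
    for f in range(1, n_frames):
        if bind_frame is not None and f >= bind_frame:
            z[f] = pin_z
        else:
            zf = z[f - 1] + rng.normal(scale=step_sd)
            if zf > hi:
                zf = 2 * hi - zf
            if zf < lo:
                zf = 2 * lo - zf
            z[f] = min(max(zf, lo), hi)
    if bind_frame is not None and bind_frame == 0:
        z[0] = pin_z
    if bind_frame is not None and bind_frame < n_frames:
        z[bind_frame:] = pin_z + rng.normal(scale=jitter, size=n_frames - bind_frame)
    truth = GroundTruth(
        frozen=np.empty((0, 0), bool),
        front_y=np.empty(0),
        front_heights=np.empty((0, 0)),
        sites=np.empty((0, 3)),
        bind_time=None if bind_frame is None or bind_frame >= n_frames
        else float(times[bind_frame]),
    )
    return times, z, truth


# ---------------------------------------------------------------------------
# ordered bridging-water fixture

_TET_HALF = 54.735  # half tetrahedral angle, degrees
_R_HB = 2.8  # ideal O...O hydrogen-bond length, A
_R_OH = 0.9572


@dataclass
class OrderedWaterFixture:
    """A planted prism-face / threonine-row / bridging-water geometry.

    ``water_o``/``water_h`` hold the ice patch followed by the bridging
    waters (and optional bulk liquid waters); ``truth_members`` are the
    indices of the planted bridges.  ``lattice_sites`` are idealised
    continuation sites of the bulk ice lattice, for reporting how far the
    bridging waters sit from regular ice positions.
    """

    water_o: np.ndarray
    water_h: np.ndarray
    ice_mask: np.ndarray
    ibs_o: np.ndarray
    ibs_h: np.ndarray
    box: np.ndarray
    truth_members: np.ndarray
    lattice_sites: np.ndarray
    thr_resids: np.ndarray


def generate_ordered_water_fixture(
    n_bridge: int = 6,
    spacing: float = 4.5,
    n_bulk: int = 0,
    seed: int = 0,
) -> OrderedWaterFixture:
    """Plant ``n_bridge`` bridging waters between an ice patch and a Thr row.

    Each bridge sits above the prism-face patch with two donated hydrogen
    bonds to ice oxygens below and two accepted hydrogen bonds from
    threonine hydroxyls above, at ``spacing`` A intervals along the
    a-axis (x).  The geometry is idealised (exact bond lengths and
    angles); infeasible combinations raise ValueError.
    """
    if n_bridge < 0:
        raise ValueError("n_bridge must be >= 0")
    if n_bridge and spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    dy = _R_HB * math.sin(math.radians(_TET_HALF))
    dz = _R_HB * math.cos(math.radians(_TET_HALF))

    box = np.array([max(n_bridge, 2) * spacing + 10.0, 30.0, 40.0])
    y_mid = box[1] / 2.0
    z_face = 8.0
    xs = 5.0 + spacing * np.arange(max(n_bridge, 1))

    ice_o, bridge_o, thr_o = [], [], []
    for x in xs:
        ice_o.append([x, y_mid - dy, z_face])
        ice_o.append([x, y_mid + dy, z_face])
    # a lower ice layer so the patch looks like a face, not a line
    for x in xs:
        for ddy in (-1.5 * dy, 0.0, 1.5 * dy):
            ice_o.append([x + spacing / 2.0, y_mid + ddy, z_face - 2.75])
    ice_o = np.array(ice_o)

    if n_bridge:
        bridge_o = np.column_stack(
            [xs[:n_bridge], np.full(n_bridge, y_mid), np.full(n_bridge, z_face + dz)]
        )
        thr_o = np.concatenate(
            [
                np.column_stack(
                    [xs[:n_bridge], np.full(n_bridge, y_mid - dy),
                     np.full(n_bridge, z_face + 2 * dz)]
                ),
                np.column_stack(
                    [xs[:n_bridge], np.full(n_bridge, y_mid + dy),
                     np.full(n_bridge, z_face + 2 * dz)]
                ),
            ]
        )
    else:
        bridge_o = np.empty((0, 3))
        thr_o = np.empty((0, 3))

    def oh(origin, target):
        v = np.asarray(target) - np.asarray(origin)
        return np.asarray(origin) + _R_OH * v / np.linalg.norm(v)

    water_o = [*ice_o, *bridge_o]
    water_h = []
    for p in ice_o:  # ice protons point down, away from the bridges
        water_h.append([p + [0.3, 0.3, -0.85], p + [-0.3, -0.3, -0.85]])
    for i, b in enumerate(bridge_o):  # bridges donate to both ice partners
        water_h.append([oh(b, ice_o[2 * i]), oh(b, ice_o[2 * i + 1])])

    ibs_h = np.array([oh(t, bridge_o[i % max(n_bridge, 1)]) for i, t in enumerate(thr_o)])
    if n_bridge == 0:
        ibs_h = np.empty((0, 3))
        thr_o = np.array([[5.0, y_mid, z_face + 15.0], [10.0, y_mid, z_face + 15.0]])
        ibs_h = thr_o + np.array([0.0, 0.0, -_R_OH])

    if n_bulk:
        bulk = rng.uniform([0, 0, z_face + 8.0], [box[0], box[1], box[2] - 1.0],
                           size=(n_bulk, 3))
        water_o.extend(bulk)
        for p in bulk:
            water_h.append([p + [0.0, 0.0, 0.96], p + [0.91, 0.0, -0.3]])

    water_o = np.array(water_o)
    water_h = np.array(water_h)
    ice_mask = np.zeros(len(water_o), dtype=bool)
    ice_mask[: len(ice_o)] = True
    truth = np.arange(len(ice_o), len(ice_o) + n_bridge)

    # ideal continuation of the bulk lattice: the next layer directly above
    lattice_sites = ice_o + np.array([0.0, 0.0, 2.75])
    thr_resids = np.array([7, 23, 39, 54, 69, 84, 101][: len(thr_o)])
    return OrderedWaterFixture(
        water_o=water_o,
        water_h=water_h,
        ice_mask=ice_mask,
        ibs_o=np.asarray(thr_o, float),
        ibs_h=np.asarray(ibs_h, float),
        box=box,
        truth_members=truth,
        lattice_sites=lattice_sites,
        thr_resids=thr_resids,
    )


# ---------------------------------------------------------------------------
# synthetic AFP structure (stand-in for a user-supplied PDB)

def make_synthetic_afp(n_residues: int = 105, loop: int = 15):
    """A synthetic beta-helix-like AFP structure for placement tests.

    This is a geometric stand-in, not a real protein model: CA atoms lie
    on a triangular coil whose axis runs along x, and the ice-binding-
    surface threonines (residues 7, 23, 39, 54, 69, 84, 101) carry OG1/HG1
    hydroxyls in a flat row on one face.
    """
    from .builder import DEFAULT_IBS_RESIDUES, ProteinStructure

    names, resnames, resids, positions = [], [], [], []
    rise = 4.5 / loop
    r = 8.0
    for i in range(n_residues):
        resid = i + 1
        ang = 2.0 * math.pi * (i % loop) / loop
        # triangular cross-section in the y-z plane
        tri = 1.0 + 0.35 * math.cos(3.0 * ang)
        y = r * tri * math.cos(ang)
        z = r * tri * math.sin(ang)
        x = i * rise
        is_thr = resid in DEFAULT_IBS_RESIDUES
        resname = "THR" if is_thr else "ALA"
        names.append("CA")
        resnames.append(resname)
        resids.append(resid)
        positions.append([x, y, z])
        if is_thr:
            og1 = [x, y * 0.9, z - 2.5 if z < 0 else -abs(z) - 2.5]
            names.append("OG1")
            resnames.append(resname)
            resids.append(resid)
            positions.append(og1)
            names.append("HG1")
            resnames.append(resname)
            resids.append(resid)
            positions.append([og1[0], og1[1], og1[2] - 0.96])
    return ProteinStructure(
        names=np.array(names),
        resnames=np.array(resnames),
        resids=np.array(resids, int),
        positions=np.array(positions, float),
        elements=np.array([n[0] for n in names]),
    )


def write_synthetic_afp_pdb(path) -> "str":
    """Write the synthetic AFP stand-in as a PDB file and return the path."""
    prot = make_synthetic_afp()
    lines = []
    for k in range(prot.n_atoms):
        x, y, z = prot.positions[k]
        lines.append(
            f"ATOM  {k + 1:5d} {prot.names[k]:<4.4s}{prot.resnames[k]:>4.4s} A"
            f"{int(prot.resids[k]):4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {prot.names[k][0]:>2.2s}\n"
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.write("".join(lines))
    return str(path)
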