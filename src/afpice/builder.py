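"""Assembly of the tilted-seed ice/water interface system.

The simulation box contains, from bottom to top: a thin disordered layer
of constrained waters (an "ice barrier" that blocks downward growth), a
constrained crystalline ice-Ih seed slab whose prism face is tilted by a
small angle about the box x-axis, mobile water filling the rest of the
box, and optionally an antifreeze protein placed above the seed with its
ice-binding surface facing down.

The tilt makes the prism plane, continued across the periodic y-boundary,
reappear an integer number of prism layers higher than where it started,
which turns layer-by-layer step growth into a continual growth mechanism
(the step can run around the periodic cell indefinitely).  To make that
consistency exact the seed's c-repeat is strained by a fraction of a
percent so that an integer number of c-repeats and the requested layer
offset together span the box length, and the tilt angle is snapped to the
corresponding arctangent.

Coordinate convention: x is the crystallographic a-axis (short box edge),
y the long axis, z the growth direction; box wrapping is half-open [0, L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.constants import N_A
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .lattice import IceLattice, LatticeSpec, assign_protons, build_ice_lattice

__all__ = [
    "SeedSpec",
    "SimulationSystem",
    "ProteinStructure",
    "PeriodicConsistencyError",
    "PlacementError",
    "DEFAULT_BOX",
    "DEFAULT_IBS_RESIDUES",
    "tilt_seed",
    "periodic_consistency",
    "build_barrier",
    "solvate",
    "place_afp",
    "build_system",
    "write_system",
    "read_system",
    "read_protein_pdb",
    "number_density",
]

#: Box of the reference interface model, A.
DEFAULT_BOX = (51.5, 126.6, 83.9)

#: Ice-binding-surface threonine residues of the spruce budworm AFP beta-helix.
DEFAULT_IBS_RESIDUES = (7, 23, 39, 54, 69, 84, 101)

CLASH_CUTOFF = 2.2  # minimum O-O separation for random water placement, A
HOH_ANGLE = 104.52  # H-O-H angle, degrees
R_OH = 0.9572


class PeriodicConsistencyError(ValueError):
    """Tilt angle incompatible with an integer layer offset across the box."""


class PlacementError(RuntimeError):
    """Random water placement could not reach the requested density."""


@dataclass(frozen=True)
class SeedSpec:
    """Geometry of the tilted seed slab.

    ``tilt_angle`` in degrees about the box x-axis; ``None`` computes the
    angle from ``step_height`` interlayer spacings across the box length.
    ``step_height`` is the number of extra prism layers in the growth step,
    ``step_extent`` the fraction of the box length the step covers and
    ``slab_thickness`` the seed thickness in A (measured perpendicular to
    the prism plane, rounded to whole layers).
    """

    tilt_angle: float | None = None
    step_height: int = 1
    step_extent: float = 0.5
    slab_thickness: float = 8.5

    def __post_init__(self) -> None:
        if self.tilt_angle is not None and not 0 <= self.tilt_angle < 90:
            raise ValueError("tilt_angle must lie in [0, 90) degrees")
        if self.step_height < 0:
            raise ValueError("step_height must be >= 0")
        if not 0 <= self.step_extent <= 1:
            raise ValueError("step_extent must lie in [0, 1]")


@dataclass
class ProteinStructure:
    """Minimal per-atom protein record set (names/resids/positions)."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    positions: np.ndarray
    elements: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class SimulationSystem:
    """Assembled ice/water interface box.

    Waters are split into three disjoint groups: ``seed`` (harmonically
    constrained crystalline ice), ``barrier`` (constrained disordered
    layer) and ``free``.  Hydrogen arrays have shape (n, 2, 3).
    """

    box: np.ndarray
    seed_o: np.ndarray
    barrier_o: np.ndarray
    free_o: np.ndarray
    seed_h: np.ndarray | None = None
    barrier_h: np.ndarray | None = None
    free_h: np.ndarray | None = None
    afp: ProteinStructure | None = None
    ibs_atoms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_waters(self) -> int:
        return len(self.seed_o) + len(self.barrier_o) + len(self.free_o)

    @property
    def seed_top_z(self) -> float:
        return float(np.max(self.seed_o[:, 2]))


def number_density(mass_density: float, M_w: float = 0.018) -> float:
    """Molecules per A^3 at the given mass density (kg/m^3)."""
    return mass_density / M_w * N_A * 1e-30


def _slab_frame(lattice: IceLattice) -> tuple[np.ndarray, np.ndarray | None]:
    """Permute crystal-frame coordinates (a->x, c->z) into the slab frame
    (a->x, c->y, prism-layer normal->z)."""
    perm = [0, 2, 1]
    oxy = lattice.oxygens[:, perm].copy()
    pro = lattice.protons[:, :, perm].copy() if lattice.protons is not None else None
    return oxy, pro


def _resolve_tilt(
    seed_spec: SeedSpec, box, a: float, c: float, validate: bool = True
) -> tuple[float, int, int, float]:
    """Snap the tilt to an exactly periodic (theta, n_layers, m_repeats, c_eff)."""
    L_y = box[1]
    d_layer = math.sqrt(3.0) / 2.0 * a
    if seed_spec.tilt_angle is None:
        n = seed_spec.step_height
    else:
        n_impl = L_y * math.sin(math.radians(seed_spec.tilt_angle)) / d_layer
        n = int(round(n_impl))
        if validate and abs(n_impl - n) > 0.25:
            raise PeriodicConsistencyError(
                f"tilt {seed_spec.tilt_angle} deg implies a rise of {n_impl:.2f} prism "
                f"layers across L_y={L_y} A, more than 0.25 layers from an integer; "
                "growth steps would not reconnect across the periodic boundary"
            )
    span = math.sqrt(max(L_y**2 - (n * d_layer) ** 2, 0.0))
    m = max(1, int(round(span / c)))
    c_eff = span / m
    theta = math.degrees(math.atan2(n * d_layer, m * c_eff))
    return theta, n, m, c_eff


def tilt_seed(
    lattice: IceLattice,
    seed_spec: SeedSpec,
    box,
    base_z: float = 5.5,
    validate: bool = True,
) -> IceLattice:
    """Tilt, strain and trim a crystal-frame lattice into the seed slab.

    The input block must be large enough to cover the box footprint after
    rotation (an extra c-repeat and a-repeat of margin is enough).  The
    returned lattice lives in the slab frame with its base at ``base_z``;
    its ``meta`` records the snapped tilt angle, layer offset and c-strain.
    """
    box = np.asarray(box, float)
    a, c = lattice.a, lattice.c
    d_layer = math.sqrt(3.0) / 2.0 * a
    theta, n, m, c_eff = _resolve_tilt(seed_spec, box, a, c, validate=validate)
    if seed_spec.tilt_angle is not None and not validate:
        theta = seed_spec.tilt_angle

    oxy, pro = _slab_frame(lattice)
    # strain the c-direction (now y) so m repeats plus the layer offset span L_y
    oxy[:, 1] *= c_eff / c
    if pro is not None:
        pro[:, :, 1] *= c_eff / c

    y_margin = c
    oxy[:, 1] -= y_margin
    if pro is not None:
        pro[:, :, 1] -= y_margin

    if np.ptp(oxy[:, 0]) + a < box[0] or np.ptp(oxy[:, 1]) < box[1] + c:
        raise ValueError(
            "lattice block too small for the box footprint; build it with more repeats"
        )

    K = max(1, int(round(seed_spec.slab_thickness / d_layer)))
    z0 = oxy[:, 2].min()
    layer = np.floor((oxy[:, 2] - z0 + 0.05 * d_layer) / d_layer).astype(int)
    th = math.radians(theta)
    step_len = seed_spec.step_extent * box[1]
    in_step = (layer == K) & (oxy[:, 1] >= 0) & (oxy[:, 1] < step_len)
    keep = (layer < K) | (in_step if seed_spec.step_height > 0 else False)
    keep &= (oxy[:, 0] >= 0) & (oxy[:, 0] < box[0])
    y_rot = oxy[:, 1] * math.cos(th) - oxy[:, 2] * math.sin(th)
    keep &= (y_rot >= 0) & (y_rot < box[1])

    oxy = oxy[keep]
    pro = pro[keep] if pro is not None else None

    rot = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(th), -math.sin(th)],
            [0.0, math.sin(th), math.cos(th)],
        ]
    )
    oxy = oxy @ rot.T
    if pro is not None:
        pro = pro @ rot.T
    shift = base_z - oxy[:, 2].min()
    oxy[:, 2] += shift
    if pro is not None:
        pro[:, :, 2] += shift

    c_axis = rot @ np.array([0.0, 1.0, 0.0])
    return IceLattice(
        oxygens=oxy,
        cell=box.copy(),
        a_axis=np.array([1.0, 0.0, 0.0]),
        c_axis=c_axis,
        a=a,
        c=c_eff,
        bond_pairs=np.empty((0, 2), int),
        bond_shifts=np.empty((0, 3), int),
        protons=pro,
        meta={
            "tilt_deg": theta,
            "layer_offset": n,
            "c_repeats": m,
            "c_eff": c_eff,
            "c_strain": c_eff / c - 1.0,
            "n_layers": K,
            "d_layer": d_layer,
            "base_z": base_z,
        },
    )


def periodic_consistency(seed: IceLattice, box) -> dict:
    """Check the continual-growth consistency of a tilted seed slab.

    Two conditions together mean that the prism plane, continued across
    the periodic y-boundary, lands exactly ``layer_offset`` prism layers
    higher than where it started:

    1. *closure*: the box period (0, L_y, 0) equals the rotated lattice
       translation made of ``c_repeats`` c-repeats plus the layer offset,
       so wrapping in y maps the crystal onto itself;
    2. *stacking*: translating the slab by the rotated n-layer stacking
       vector of ice Ih (which carries an a/2 lateral offset for odd n --
       ABAB prism stacking) superimposes it on itself where the slabs
       overlap.

    Returns the RMSD over matched oxygens, the matched fraction and the
    closure error (A).
    """
    box = np.asarray(box, float)
    meta = seed.meta
    n = meta["layer_offset"]
    d = meta["d_layer"]
    m = meta["c_repeats"]
    c_eff = meta["c_eff"]
    th = math.radians(meta["tilt_deg"])
    rot = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(th), -math.sin(th)],
            [0.0, math.sin(th), math.cos(th)],
        ]
    )
    dx = (n * seed.a / 2.0) % seed.a
    closure = float(
        np.linalg.norm(rot @ np.array([dx, m * c_eff, -n * d]) - np.array([dx, box[1], 0.0]))
    )
    shifted = seed.oxygens + rot @ np.array([dx, 0.0, n * d])
    shifted[:, 0] = np.mod(shifted[:, 0], box[0])
    tree = cKDTree(seed.oxygens)
    dist, _ = tree.query(shifted, k=1)
    matched = dist < 0.3
    rmsd = float(np.sqrt(np.mean(dist[matched] ** 2))) if matched.any() else np.inf
    return {
        "rmsd": rmsd,
        "matched_fraction": float(matched.mean()),
        "closure_error": closure,
        "layer_offset": n,
    }


class _ClashGrid:
    """Cell-list accelerated minimum-image clash checks for water placement."""

    def __init__(self, box, cutoff: float = CLASH_CUTOFF):
        self.box = np.asarray(box, float)
        self.cutoff = cutoff
        self.n = np.maximum(np.floor(self.box / cutoff).astype(int), 1)
        self.size = self.box / self.n
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p):
        return tuple((np.floor(p / self.size).astype(int)) % self.n)

    def insert(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(p)

    def clashes(self, p: np.ndarray) -> bool:
        base = np.floor(p / self.size).astype(int)
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key = tuple((base + (ox, oy, oz)) % self.n)
                    for q in self.cells.get(key, ()):
                        d = p - q
                        d -= self.box * np.rint(d / self.box)
                        if d @ d < self.cutoff**2:
                            return True
        return False


def _random_water_hydrogens(o: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two O-H vectors with random orientation and the rigid H-O-H angle."""
    n = len(o)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = rng.normal(size=(n, 3))
    v -= (np.sum(u * v, axis=1, keepdims=True)) * u
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    ang = math.radians(HOH_ANGLE)
    h1 = o + R_OH * u
    h2 = o + R_OH * (math.cos(ang) * u + math.sin(ang) * v)
    return np.stack([h1, h2], axis=1)


def _rsa_fill(
    box,
    n_target: int,
    zlo: float,
    zhi: float,
    rng: np.random.Generator,
    existing: np.ndarray | None = None,
    attempts_per_molecule: int = 10_000,
) -> np.ndarray:
    """Random sequential placement of clash-free points in a z-slab."""
    box = np.asarray(box, float)
    grid = _ClashGrid(box)
    if existing is not None:
        for p in existing:
            grid.insert(p)
    placed = []
    budget = attempts_per_molecule * max(n_target, 1)
    attempts = 0
    while len(placed) < n_target:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(placed)}/{n_target} waters after {attempts} attempts; "
                "target density unreachable with the clash cutoff"
            )
        attempts += 1
        p = np.array(
            [
                rng.uniform(0, box[0]),
                rng.uniform(0, box[1]),
                rng.uniform(zlo, zhi),
            ]
        )
        if not grid.clashes(p):
            grid.insert(p)
            placed.append(p)
    return np.array(placed).reshape(-1, 3)


def build_barrier(
    box,
    thickness: float = 5.0,
    target_density: float = 940.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomly placed, clash-free waters filling a [0, thickness) layer.

    These model the constrained disordered "ice barrier" below the seed.
    Default density is that of (TIP4P) ice.
    """
    box = np.asarray(box, float)
    if thickness >= box[2] / 4:
        raise ValueError("barrier thickness must be below a quarter of the box height")
    if thickness <= 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_target = int(round(box[0] * box[1] * thickness * number_density(target_density)))
    return _rsa_fill(box, n_target, 0.0, thickness, rng)


def solvate(
    system: SimulationSystem,
    target_density: float = 970.0,
    seed: int | np.random.Generator = 0,
    barrier_thickness: float = 5.0,
) -> SimulationSystem:
    """Fill the remaining box volume with clash-free free waters.

    The total molecule count is set from the box volume at the target
    (supercooled liquid) density; free waters make up the difference after
    the seed and barrier groups.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    box = np.asarray(system.box, float)
    n_total = int(round(np.prod(box) * number_density(target_density)))
    n_free = n_total - len(system.seed_o) - len(system.barrier_o)
    if n_free <= 0:
        free = np.empty((0, 3))
    else:
        existing = np.vstack([system.seed_o, system.barrier_o])
        free = _rsa_fill(box, n_free, barrier_thickness, box[2], rng, existing=existing)
    return replace(
        system,
        free_o=free,
        free_h=_random_water_hydrogens(free, rng) if len(free) else np.empty((0, 2, 3)),
        meta={**system.meta, "target_density": target_density, "n_total_target": n_total},
    )


def read_protein_pdb(path: str | Path) -> ProteinStructure:
    """Read protein atoms from a PDB file (waters and ions are skipped)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        sel = u.select_atoms("not resname HOH WAT TIP3 TIP4 SOL NA CL")
        try:
            elements = sel.elements.astype(str)
        except Exception:
            elements = np.array([n[0] for n in sel.names])
    return ProteinStructure(
        names=sel.names.astype(str),
        resnames=sel.resnames.astype(str),
        resids=sel.resids.astype(int),
        positions=sel.positions.astype(float).copy(),
        elements=elements,
    )


def place_afp(
    system: SimulationSystem,
    afp: ProteinStructure,
    height: float = 20.0,
    orient_ibs_down: bool = True,
    ibs_residues=DEFAULT_IBS_RESIDUES,
    clash_cutoff: float = 2.4,
) -> SimulationSystem:
    """Place the AFP with its centre of mass ``height`` A above the seed top.

    With ``orient_ibs_down`` the mean plane of the ice-binding-surface
    threonine hydroxyl oxygens is turned to face the seed and the T-X-T
    row direction is aligned with the a-axis (box x).  Free waters whose
    oxygen falls within ``clash_cutoff`` of any protein atom are deleted.
    """
    ibs_mask = np.isin(afp.resids, np.asarray(ibs_residues)) & (afp.names == "OG1")
    found = set(afp.resids[ibs_mask].tolist())
    missing = [r for r in ibs_residues if r not in found]
    if missing:
        raise ValueError(f"ice-binding-surface residues without OG1 atoms: {missing}")

    pos = afp.positions.copy()
    com = pos.mean(axis=0)
    pos -= com
    if orient_ibs_down:
        ibs_centroid = pos[ibs_mask].mean(axis=0)
        rot1, _ = Rotation.align_vectors([[0.0, 0.0, -1.0]], [ibs_centroid])
        pos = rot1.apply(pos)
        # align the threonine-row direction with x by a rotation about z
        row = pos[ibs_mask]
        row = row - row.mean(axis=0)
        direction = np.linalg.svd(row[:, :2], full_matrices=False)[2][0]
        ang = math.atan2(direction[1], direction[0])
        rotz = Rotation.from_euler("z", -ang)
        pos = rotz.apply(pos)

    box = np.asarray(system.box, float)
    target = np.array([box[0] / 2.0, box[1] / 2.0, system.seed_top_z + height])
    pos += target

    if (pos.min(axis=0) < 0).any() or (pos.max(axis=0) > box).any():
        raise ValueError("AFP does not fit inside the box at the requested height")

    placed = ProteinStructure(
        names=afp.names.copy(),
        resnames=afp.resnames.copy(),
        resids=afp.resids.copy(),
        positions=pos,
        elements=None if afp.elements is None else afp.elements.copy(),
    )
    keep = np.ones(len(system.free_o), dtype=bool)
    if len(system.free_o):
        tree = cKDTree(pos)
        d, _ = tree.query(system.free_o, k=1)
        keep = d >= clash_cutoff
    return replace(
        system,
        afp=placed,
        ibs_atoms=np.nonzero(ibs_mask)[0],
        free_o=system.free_o[keep],
        free_h=None if system.free_h is None else system.free_h[keep],
        meta={**system.meta, "afp_height": height, "n_waters_deleted": int((~keep).sum())},
    )


def build_system(
    box=DEFAULT_BOX,
    lattice_spec: LatticeSpec | None = None,
    seed_spec: SeedSpec | None = None,
    barrier_thickness: float = 5.0,
    target_density: float = 970.0,
    barrier_density: float = 940.0,
    afp: ProteinStructure | None = None,
    afp_height: float = 20.0,
    seed: int = 0,
) -> SimulationSystem:
    """Assemble barrier + tilted seed + free water (+ optional AFP)."""
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    if lattice_spec is None:
        lattice_spec = LatticeSpec()
    if seed_spec is None:
        seed_spec = SeedSpec()
    d_layer = math.sqrt(3.0) / 2.0 * lattice_spec.a
    n_a = int(math.ceil(box[0] / lattice_spec.a)) + 1
    n_c = int(math.ceil((box[1] + 5 * lattice_spec.c) / lattice_spec.c)) + 1
    n_layers = int(round(seed_spec.slab_thickness / d_layer)) + seed_spec.step_height + 1
    n_b = max(1, int(math.ceil(n_layers * d_layer / (math.sqrt(3.0) * lattice_spec.a))) + 1)
    block = build_ice_lattice(
        LatticeSpec(
            a=lattice_spec.a, c=lattice_spec.c, n_a=n_a, n_b=n_b, n_c=n_c,
            proton_seed=lattice_spec.proton_seed,
        )
    )
    block = assign_protons(block, seed=lattice_spec.proton_seed)
    slab = tilt_seed(block, seed_spec, box, base_z=barrier_thickness + 0.5)
    barrier = build_barrier(box, barrier_thickness, barrier_density, rng)
    system = SimulationSystem(
        box=box,
        seed_o=slab.oxygens,
        seed_h=slab.protons,
        barrier_o=barrier,
        barrier_h=_random_water_hydrogens(barrier, rng),
        free_o=np.empty((0, 3)),
        meta={"seed_meta": slab.meta, "seed_slab": slab, "rng_seed": seed},
    )
    system = solvate(system, target_density, rng, barrier_thickness)
    if afp is not None:
        system = place_afp(system, afp, height=afp_height)
    return system


# ---------------------------------------------------------------------------
# structure file output

_MD_SETTINGS_STUB = {
    "engine": "external (not run by this package)",
    "water_model": "TIP4P",
    "forcefield": "CHARMM22",
    "ensemble": "NPT",
    "pressure_bar": 1.0,
    "thermostat": "Langevin",
    "barostat": "Nose-Hoover Langevin piston (period 100 fs, decay 50 fs)",
    "timestep_fs": 2.0,
    "electrostatics": "PME, 1.0 A grid",
    "cutoff_A": 12.0,
    "switching_A": 10.0,
    "pairlist_A": 14.0,
    "constraints": "SHAKE on hydrogens; harmonic restraints on seed and barrier waters",
    "frame_interval_ps": 100.0,
}


def _pdb_atom_line(serial, name, resname, chain, resid, xyz, bfac, element=""):
    x, y, z = xyz
    if not (-999.999 <= min(x, y, z) and max(x, y, z) <= 9999.999):
        raise ValueError(f"coordinate {xyz} exceeds fixed-column PDB field width")
    return (
        f"ATOM  {serial % 100000:5d} {name:<4.4s}{resname:>4.4s} {chain}{resid % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfac:6.2f}          {element:>2.2s}\n"
    )


def write_system(system: SimulationSystem, prefix: str | Path, provenance: dict | None = None):
    """Write ``<prefix>.pdb``, ``<prefix>_constraints.csv`` and ``<prefix>_meta.yaml``.

    Constraint flags are encoded in the B-factor column (1.0 = harmonically
    constrained, 0.0 = free); the CSV lists constrained atom indices with
    their reference positions.  Returns the paths written.
    """
    import pandas as pd

    prefix = Path(prefix)
    pdb_path = prefix.with_suffix(".pdb")
    lines = [
        "CRYST1{:9.3f}{:9.3f}{:9.3f}  90.00  90.00  90.00 P 1           1\n".format(
            *np.asarray(system.box, float)
        )
    ]
    serial = 1
    resid = 1
    constrained_rows = []
    if system.afp is not None:
        for k in range(system.afp.n_atoms):
            el = "" if system.afp.elements is None else system.afp.elements[k]
            lines.append(
                _pdb_atom_line(
                    serial, system.afp.names[k], system.afp.resnames[k], "A",
                    int(system.afp.resids[k]), system.afp.positions[k], 0.0, el,
                )
            )
            serial += 1

    def emit_waters(o, h, chain, bfac):
        nonlocal serial, resid
        for k in range(len(o)):
            lines.append(_pdb_atom_line(serial, "O", "HOH", chain, resid, o[k], bfac, "O"))
            if bfac > 0.5:
                constrained_rows.append((serial - 1, chain, *o[k]))
            serial += 1
            if h is not None:
                for hk in range(2):
                    lines.append(
                        _pdb_atom_line(serial, f"H{hk + 1}", "HOH", chain, resid, h[k, hk], bfac, "H")
                    )
                    serial += 1
            resid += 1

    emit_waters(system.seed_o, system.seed_h, "S", 1.0)
    emit_waters(system.barrier_o, system.barrier_h, "B", 1.0)
    emit_waters(system.free_o, system.free_h, "W", 0.0)
    lines.append("END\n")
    pdb_path.write_text("".join(lines))

    csv_path = prefix.parent / (prefix.name + "_constraints.csv")
    pd.DataFrame(
        constrained_rows, columns=["atom_index", "group", "x_ref", "y_ref", "z_ref"]
    ).to_csv(csv_path, index=False)

    meta_path = prefix.parent / (prefix.name + "_meta.yaml")
    meta = {
        "md_settings": _MD_SETTINGS_STUB,
        "box": [float(v) for v in system.box],
        "counts": {
            "seed": len(system.seed_o),
            "barrier": len(system.barrier_o),
            "free": len(system.free_o),
            "total_waters": system.n_waters,
            "afp_atoms": 0 if system.afp is None else system.afp.n_atoms,
        },
    }
    if provenance:
        meta["provenance"] = provenance
    seed_meta = system.meta.get("seed_meta")
    if seed_meta:
        meta["seed_geometry"] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in seed_meta.items()
        }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return pdb_path, csv_path, meta_path


def read_system(path: str | Path) -> SimulationSystem:
    """Read a system PDB written by :func:`write_system` back into memory."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    def waters(chain):
        o = u.select_atoms(f"chainID {chain} and resname HOH and name O")
        h = u.select_atoms(f"chainID {chain} and resname HOH and name H1 H2")
        opos = o.positions.astype(float).copy()
        hpos = (
            h.positions.astype(float).reshape(len(opos), 2, 3).copy() if len(h) else None
        )
        return opos, hpos

    seed_o, seed_h = waters("S")
    barrier_o, barrier_h = waters("B")
    free_o, free_h = waters("W")
    prot = u.select_atoms("chainID A")
    afp = None
    if len(prot):
        afp = ProteinStructure(
            names=prot.names.astype(str),
            resnames=prot.resnames.astype(str),
            resids=prot.resids.astype(int),
            positions=prot.positions.astype(float).copy(),
        )
    box = u.dimensions[:3].astype(float) if u.dimensions is not None else None
    return SimulationSystem(
        box=box,
        seed_o=seed_o,
        seed_h=seed_h,
        barrier_o=barrier_o,
        barrier_h=barrier_h,
        free_o=free_o,
        free_h=free_h,
        afp=afp,
    )
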