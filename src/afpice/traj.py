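"""Trajectory container and multi-frame file I/O.

A :class:`Trajectory` holds ordered frames of labelled particle
coordinates at a fixed inter-frame time (default 100 ps).  Each atom
carries a role:

========  =======================================
``WO``    water oxygen (mobile)
``WH``    water hydrogen
``PRO``   protein atom
``SEED``  constrained crystalline seed water oxygen
``BARR``  constrained barrier water oxygen
========  =======================================

Supported on-disk formats:

* an XYZ dialect in which the comment line carries the frame time and box
  (``t= <ps> box= <Lx> <Ly> <Lz>``) and the atom-label column carries the
  role token directly;
* multi-frame PDB (MODEL/ENDMDL) with roles encoded in the chain ID
  (A=protein, S=seed, B=barrier, W=free water), read through MDAnalysis;
* binary DCD with a companion topology PDB, read through MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ROLE_WATER_O",
    "ROLE_WATER_H",
    "ROLE_PROTEIN",
    "ROLE_SEED",
    "ROLE_BARRIER",
    "Trajectory",
    "write_xyz",
    "read_xyz",
    "write_pdb_trajectory",
    "read_trajectory",
]

ROLE_WATER_O = "WO"
ROLE_WATER_H = "WH"
ROLE_PROTEIN = "PRO"
ROLE_SEED = "SEED"
ROLE_BARRIER = "BARR"

_ALL_ROLES = (ROLE_WATER_O, ROLE_WATER_H, ROLE_PROTEIN, ROLE_SEED, ROLE_BARRIER)

#: roles whose particles are water oxygens (mobile or constrained)
OXYGEN_ROLES = (ROLE_WATER_O, ROLE_SEED, ROLE_BARRIER)


@dataclass
class Trajectory:
    """Ordered frames of labelled coordinates with a fixed frame interval.

    Attributes
    ----------
    coords : (F, N, 3) array
        Coordinates in A.
    box : (3,) array
        Periodic box lengths (x and y periodic; z treated as bounded).
    dt_frame : float
        Inter-frame time, ps.
    roles : (N,) array of str
        Role token per atom (constant across frames).
    times : (F,) array
        Frame times in ps; defaults to ``arange(F) * dt_frame``.
    """

    coords: np.ndarray
    box: np.ndarray
    dt_frame: float = 100.0
    roles: np.ndarray | None = None
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not self.dt_frame > 0:
            raise ValueError("dt_frame must be positive")
        self.box = np.asarray(self.box, float)
        if self.roles is None:
            self.roles = np.full(self.coords.shape[1], ROLE_WATER_O, dtype="<U4")
        else:
            self.roles = np.asarray(self.roles, dtype="<U4")
            if len(self.roles) != self.coords.shape[1]:
                raise ValueError("one role per atom is required")
            unknown = set(self.roles.tolist()) - set(_ALL_ROLES)
            if unknown:
                raise ValueError(f"unknown roles: {sorted(unknown)}")
        if self.times is None:
            self.times = np.arange(self.n_frames) * self.dt_frame
        else:
            self.times = np.asarray(self.times, float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atoms_with_role(self, *roles: str) -> np.ndarray:
        return np.nonzero(np.isin(self.roles, roles))[0]

    @property
    def water_oxygens(self) -> np.ndarray:
        """Indices of all water oxygens, mobile and constrained."""
        return self.atoms_with_role(*OXYGEN_ROLES)

    @property
    def mobile_oxygens(self) -> np.ndarray:
        return self.atoms_with_role(ROLE_WATER_O)

    @property
    def protein_atoms(self) -> np.ndarray:
        return self.atoms_with_role(ROLE_PROTEIN)

    def seed_top_z(self) -> float:
        """Height of the topmost constrained seed oxygen (frame 0).

        The seed is harmonically constrained, so this plane is static and
        is computed once per trajectory.
        """
        idx = self.atoms_with_role(ROLE_SEED)
        if len(idx) == 0:
            raise ValueError("trajectory has no constrained-seed atoms")
        return float(self.coords[0, idx, 2].max())

    def time_slice(self, t_start: float, t_end: float) -> "Trajectory":
        mask = (self.times >= t_start) & (self.times <= t_end)
        return Trajectory(
            coords=self.coords[mask],
            box=self.box,
            dt_frame=self.dt_frame,
            roles=self.roles,
            times=self.times[mask],
            meta=dict(self.meta),
        )

    def reversed(self) -> "Trajectory":
        return Trajectory(
            coords=self.coords[::-1].copy(),
            box=self.box,
            dt_frame=self.dt_frame,
            roles=self.roles,
            times=self.times[0] + (self.times[-1] - self.times[::-1]),
            meta=dict(self.meta),
        )


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write the documented XYZ dialect (role token as the atom label)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                "t= {:.3f} box= {:.4f} {:.4f} {:.4f}\n".format(
                    traj.times[f], *traj.box
                )
            )
            for role, (x, y, z) in zip(traj.roles, traj.coords[f]):
                fh.write(f"{role:<4s} {x:12.4f} {y:12.4f} {z:12.4f}\n")
    return path


def read_xyz(path: str | Path, dt_frame: float | None = None) -> Trajectory:
    """Read the XYZ dialect written by :func:`write_xyz`."""
    frames, times = [], []
    box = None
    roles = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            t = float(comment[comment.index("t=") + 1])
            b = comment.index("box=")
            box = np.array([float(v) for v in comment[b + 1 : b + 4]])
            frame_roles = np.empty(n, dtype="<U4")
            xyz = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                frame_roles[i] = parts[0]
                xyz[i] = [float(v) for v in parts[1:4]]
            if roles is None:
                roles = frame_roles
            elif not np.array_equal(roles, frame_roles):
                raise ValueError("atom roles change between frames")
            frames.append(xyz)
            times.append(t)
    times = np.array(times)
    if dt_frame is None:
        dt_frame = float(times[1] - times[0]) if len(times) > 1 else 100.0
    return Trajectory(
        coords=np.array(frames), box=box, dt_frame=dt_frame, roles=roles, times=times
    )


_ROLE_TO_CHAIN = {ROLE_PROTEIN: "A", ROLE_SEED: "S", ROLE_BARRIER: "B",
                  ROLE_WATER_O: "W", ROLE_WATER_H: "W"}


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a multi-frame PDB (MODEL/ENDMDL) with roles in the chain ID."""
    path = Path(path)
    names = np.where(traj.roles == ROLE_WATER_H, "H", "O")
    names = np.where(traj.roles == ROLE_PROTEIN, "CA", names)
    resnames = np.where(traj.roles == ROLE_PROTEIN, "ALA", "HOH")
    chains = np.array([_ROLE_TO_CHAIN[r] for r in traj.roles])
    with open(path, "w") as fh:
        fh.write(
            "CRYST1{:9.3f}{:9.3f}{:9.3f}  90.00  90.00  90.00 P 1           1\n".format(
                *traj.box
            )
        )
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                fh.write(
                    f"ATOM  {(i + 1) % 100000:5d} {names[i]:<4.4s}{resnames[i]:>4.4s} "
                    f"{chains[i]}{(i + 1) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def _read_mdanalysis(path: Path, top: Path | None, dt_frame: float) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(top), str(path)) if top is not None else mda.Universe(str(path))
        chains = None
        try:
            chains = u.atoms.chainIDs.astype(str)
        except Exception:
            pass
        names = u.atoms.names.astype(str)
        roles = np.full(len(u.atoms), ROLE_WATER_O, dtype="<U4")
        is_h = np.char.startswith(names, "H")
        roles[is_h] = ROLE_WATER_H
        if chains is not None:
            roles[chains == "A"] = ROLE_PROTEIN
            roles[(chains == "S") & ~is_h] = ROLE_SEED
            roles[(chains == "B") & ~is_h] = ROLE_BARRIER
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        box = (
            u.dimensions[:3].astype(float)
            if u.dimensions is not None and u.dimensions[:3].any()
            else np.ptp(coords[0], axis=0)
        )
    return Trajectory(coords=coords, box=box, dt_frame=dt_frame, roles=roles)


def read_trajectory(
    path: str | Path, top: str | Path | None = None, dt_frame: float | None = None
) -> Trajectory:
    """Read a trajectory, dispatching on the file extension.

    ``.xyz`` uses the package's documented dialect; ``.pdb`` reads
    multi-frame PDB; ``.dcd`` requires a companion topology PDB via
    ``top``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path, dt_frame=dt_frame)
    if suffix == ".pdb":
        return _read_mdanalysis(path, None, dt_frame or 100.0)
    if suffix == ".dcd":
        if top is None:
            raise ValueError("DCD trajectories need a companion topology PDB (top=...)")
        return _read_mdanalysis(path, Path(top), dt_frame or 100.0)
    raise ValueError(f"unsupported trajectory format: {path.suffix}")
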