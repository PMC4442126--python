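"""Hexagonal ice (Ih) lattice generation with proton disorder.

Oxygens are placed on the wurtzite-type ice-Ih lattice using an
orthorhombic supercell of dimensions ``a x sqrt(3)*a x c`` containing
eight molecules, with the crystallographic a-axis along x and the c-axis
along z.  Protons are then assigned so that the Bernal-Fowler ice rules
hold on every (periodic) hydrogen bond:

* rule I  - every oxygen carries exactly two covalent hydrogens,
* rule II - every hydrogen-bonded O-O pair carries exactly one proton.

Ice rules are equivalent to an orientation of the 4-regular O-O bond
graph in which every vertex has in-degree and out-degree 2 (the donated
proton sits on the directed edge).  Such an orientation is obtained
exactly by walking an Eulerian circuit of the bond graph; proton disorder
comes from seeding the circuit's edge choices, and the net cell dipole is
then reduced below a threshold by reversing randomly chosen directed
loops (loop reversal preserves both ice rules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LatticeSpec",
    "IceLattice",
    "ProtonAssignmentError",
    "build_ice_lattice",
    "find_bonds",
    "assign_protons",
    "ice_rule_defects",
    "translation_period",
]

#: Fractional coordinates of the 8 oxygens of the orthorhombic ice-Ih cell
#: (a-axis along x, c-axis along z; ideal wurtzite internal parameter 3/8).
ORTHO_FRAC = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 3.0 / 8.0],
        [0.5, 1.0 / 6.0, 0.5],
        [0.5, 1.0 / 6.0, 7.0 / 8.0],
        [0.5, 0.5, 0.0],
        [0.5, 0.5, 3.0 / 8.0],
        [0.0, 2.0 / 3.0, 0.5],
        [0.0, 2.0 / 3.0, 7.0 / 8.0],
    ]
)

R_OH = 0.9572  # covalent O-H length, Angstrom (TIP4P-style rigid geometry)


class ProtonAssignmentError(RuntimeError):
    """Raised when a proton configuration cannot satisfy the requested criteria."""


@dataclass(frozen=True)
class LatticeSpec:
    """Size and lattice constants of an ice-Ih block.

    ``a`` and ``c`` default to the rounded repeats 4.5 / 7.4 A observed on
    the prism face; the crystallographic values 4.497 / 7.324 A are
    available as ``LatticeSpec.crystallographic()``.
    """

    a: float = 4.5
    c: float = 7.4
    n_a: int = 1
    n_b: int = 1
    n_c: int = 1
    proton_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0):
            raise ValueError("lattice constants must be positive")
        if min(self.n_a, self.n_b, self.n_c) < 1:
            raise ValueError("repeat counts must be >= 1")

    @classmethod
    def crystallographic(cls, **kw) -> "LatticeSpec":
        return cls(a=4.497, c=7.324, **kw)


@dataclass
class IceLattice:
    """An ice-Ih block: oxygen sites, bond topology, optional protons.

    Attributes
    ----------
    oxygens : (N, 3) array
        Oxygen positions, A.
    cell : (3,) array
        Orthorhombic periodic cell lengths, A.
    a_axis, c_axis : (3,) arrays
        Unit vectors of the crystallographic a- and c-axes.
    a, c : float
        Lattice repeats along those axes, A.
    bond_pairs : (B, 2) int array
        Oxygen indices of each hydrogen bond.
    bond_shifts : (B, 3) int array
        Periodic image shift of the second oxygen of each bond (so the
        bond vector is ``oxygens[j] + bond_shifts @ diag(cell) - oxygens[i]``).
    bond_donor : (B,) int array or None
        0 if ``bond_pairs[b, 0]`` donates the proton on bond b, 1 otherwise.
    protons : (N, 2, 3) array or None
        Hydrogen positions per oxygen once assigned.
    meta : dict
        Free-form provenance (tilt angle, strain, ...).
    """

    oxygens: np.ndarray
    cell: np.ndarray
    a_axis: np.ndarray
    c_axis: np.ndarray
    a: float
    c: float
    bond_pairs: np.ndarray
    bond_shifts: np.ndarray
    bond_donor: np.ndarray | None = None
    protons: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_oxygens(self) -> int:
        return len(self.oxygens)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_pairs)

    def bond_vectors(self) -> np.ndarray:
        """(B, 3) vectors from the first to the second oxygen of each bond."""
        i, j = self.bond_pairs.T
        return self.oxygens[j] + self.bond_shifts * self.cell - self.oxygens[i]


def build_ice_lattice(spec: LatticeSpec) -> IceLattice:
    """Generate the oxygen sublattice of an ice-Ih block (protons unassigned).

    The block tiles the 8-molecule orthorhombic cell ``n_a x n_b x n_c``
    times; the periodic cell is ``(n_a*a, n_b*sqrt(3)*a, n_c*c)``.
    """
    ratio = spec.c / spec.a
    if not 1.4 <= ratio <= 1.9:
        warnings.warn(
            f"c/a = {ratio:.3f} is far from the ideal hexagonal ratio ~1.63; "
            "the lattice will be strongly strained",
            stacklevel=2,
        )
    cell = np.array([spec.n_a * spec.a, spec.n_b * np.sqrt(3.0) * spec.a, spec.n_c * spec.c])
    unit = np.array([spec.a, np.sqrt(3.0) * spec.a, spec.c])
    shifts = np.stack(
        np.meshgrid(
            np.arange(spec.n_a), np.arange(spec.n_b), np.arange(spec.n_c), indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    oxygens = (ORTHO_FRAC[None, :, :] + shifts[:, None, :]).reshape(-1, 3) * unit
    pairs, img = find_bonds(oxygens, cell)
    return IceLattice(
        oxygens=oxygens,
        cell=cell,
        a_axis=np.array([1.0, 0.0, 0.0]),
        c_axis=np.array([0.0, 0.0, 1.0]),
        a=spec.a,
        c=spec.c,
        bond_pairs=pairs,
        bond_shifts=img,
        meta={"spec": spec},
    )


def find_bonds(oxygens: np.ndarray, cell: np.ndarray, cutoff: float | None = None):
    """Periodic nearest-neighbour O-O bonds as (pairs, image_shifts).

    Multi-edges through different periodic images (possible in very small
    cells) are kept as distinct bonds, so the enumeration is done over
    explicit image shifts rather than minimum-image distances.
    """
    n = len(oxygens)
    if cutoff is None:
        # nearest-neighbour O-O is ~2.76 A for the default constants; next
        # shell is > 4 A, so 3.2 A separates them for any sane (a, c)
        cutoff = 3.2
    pairs: list[tuple[int, int]] = []
    imgs: list[np.ndarray] = []
    shift_grid = np.stack(
        np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    if n <= 512 or np.min(cell) < 2.0 * cutoff:
        for s in shift_grid:
            disp = oxygens[None, :, :] + s * cell - oxygens[:, None, :]
            d = np.linalg.norm(disp, axis=-1)
            ii, jj = np.nonzero(d < cutoff)
            for i, j in zip(ii, jj):
                if i < j or (i == j and tuple(s) > (0, 0, 0)):
                    pairs.append((i, j))
                    imgs.append(s.copy())
                elif i == j and tuple(s) == (0, 0, 0):
                    continue
                elif i > j:
                    continue  # counted as (j, i, -s)
    else:
        wrapped = np.mod(oxygens, cell)
        tree = cKDTree(wrapped, boxsize=cell)
        for i, j in tree.query_pairs(cutoff):
            d = wrapped[j] - wrapped[i]
            s = -np.rint(d / cell).astype(int)
            # recover the unwrapped image shift for the stored coordinates
            s_unwrapped = s + np.rint(
                ((oxygens[j] - wrapped[j]) - (oxygens[i] - wrapped[i])) / cell * -1
            ).astype(int)
            vec = oxygens[j] + s_unwrapped * cell - oxygens[i]
            if np.linalg.norm(vec) >= cutoff:  # pragma: no cover - safety net
                raise AssertionError("image bookkeeping failed")
            pairs.append((i, j))
            imgs.append(s_unwrapped)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(imgs, dtype=int).reshape(-1, 3)


def _euler_orientation(n: int, pairs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orient every bond along a randomised Eulerian circuit (Hierholzer).

    Each vertex of the O-O graph has even degree (4 in the periodic bulk),
    so a circuit exists per connected component; orienting edges along it
    gives out-degree = in-degree = degree/2 exactly, i.e. both ice rules.
    """
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for b, (i, j) in enumerate(pairs):
        adjacency[i].append(b)
        adjacency[j].append(b)
    for lst in adjacency:
        rng.shuffle(lst)
    used = np.zeros(len(pairs), dtype=bool)
    donor = np.zeros(len(pairs), dtype=np.int8)
    ptr = np.zeros(n, dtype=int)
    for start in range(n):
        if ptr[start] >= len(adjacency[start]):
            continue
        stack = [start]
        while stack:
            v = stack[-1]
            advanced = False
            while ptr[v] < len(adjacency[v]):
                b = adjacency[v][ptr[v]]
                ptr[v] += 1
                if used[b]:
                    continue
                used[b] = True
                i, j = pairs[b]
                w = j if i == v else i
                donor[b] = 0 if i == v else 1
                stack.append(w)
                advanced = True
                break
            if not advanced:
                stack.pop()
    if not used.all():  # pragma: no cover - graph is connected by construction
        raise ProtonAssignmentError("Eulerian orientation left unused bonds")
    return donor


def _molecular_vectors(lat: IceLattice, donor: np.ndarray) -> np.ndarray:
    """Sum of the two donated O->H unit vectors per oxygen (dipole proxy)."""
    vec = lat.bond_vectors()
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    mol = np.zeros((lat.n_oxygens, 3))
    i, j = lat.bond_pairs.T
    from_i = donor == 0
    np.add.at(mol, i[from_i], unit[from_i])
    np.add.at(mol, j[~from_i], -unit[~from_i])
    return mol


def _reduce_dipole(
    lat: IceLattice,
    donor: np.ndarray,
    rng: np.random.Generator,
    max_dipole: float,
    max_moves: int,
) -> np.ndarray:
    """Reverse random directed loops until |net dipole|/N < max_dipole.

    ``max_dipole`` is measured in units of a single molecular dipole
    (|bisector| = 2 cos(109.47/2) ~ 1.155 in O-H unit-vector units).
    """
    vec = lat.bond_vectors()
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    n = lat.n_oxygens
    mol_dipole = 2.0 * np.cos(np.deg2rad(109.47 / 2.0))
    target = max_dipole * mol_dipole * n

    out_edges: list[set[int]] = [set() for _ in range(n)]
    for b, (i, j) in enumerate(lat.bond_pairs):
        out_edges[i if donor[b] == 0 else j].add(b)

    def donated(b: int) -> np.ndarray:
        return unit[b] if donor[b] == 0 else -unit[b]

    M = np.zeros(3)
    for b in range(lat.n_bonds):
        M += donated(b)

    for _ in range(max_moves):
        if np.linalg.norm(M) < target:
            return donor
        # random walk along donated bonds until a vertex repeats -> loop
        v = int(rng.integers(n))
        path_v = [v]
        path_b: list[int] = []
        seen = {v: 0}
        while True:
            choices = list(out_edges[v])
            if not choices:  # surface vertex with no out-edges
                break
            b = choices[int(rng.integers(len(choices)))]
            i, j = lat.bond_pairs[b]
            w = int(j if donor[b] == 0 else i)
            path_b.append(b)
            if w in seen:
                k = seen[w]
                loop = path_b[k:]
                dM = -2.0 * sum(donated(bb) for bb in loop)
                if np.linalg.norm(M + dM) < np.linalg.norm(M):
                    for bb in loop:
                        i2, j2 = lat.bond_pairs[bb]
                        old = int(i2 if donor[bb] == 0 else j2)
                        new = int(j2 if donor[bb] == 0 else i2)
                        out_edges[old].discard(bb)
                        out_edges[new].add(bb)
                        donor[bb] = 1 - donor[bb]
                    M = M + dM
                break
            seen[w] = len(path_v)
            path_v.append(w)
            v = w
    if np.linalg.norm(M) >= target:
        raise ProtonAssignmentError(
            f"net dipole {np.linalg.norm(M) / (mol_dipole * n):.3f} per molecule "
            f"did not fall below {max_dipole} within {max_moves} loop moves"
        )
    return donor


def assign_protons(
    lattice: IceLattice,
    seed: int,
    max_dipole_per_molecule: float = 0.1,
    max_moves: int | None = None,
) -> IceLattice:
    """Assign a disordered, ice-rule-satisfying proton configuration.

    Returns a new :class:`IceLattice` with ``bond_donor`` and ``protons``
    populated.  Reproducible for a fixed ``seed``.  Raises
    :class:`ProtonAssignmentError` if the net-dipole criterion cannot be
    met within the move budget.
    """
    rng = np.random.default_rng(seed)
    donor = _euler_orientation(lattice.n_oxygens, lattice.bond_pairs, rng)
    if max_moves is None:
        max_moves = 500 * lattice.n_oxygens
    donor = _reduce_dipole(lattice, donor, rng, max_dipole_per_molecule, max_moves)

    vec = lattice.bond_vectors()
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    protons = np.full((lattice.n_oxygens, 2, 3), np.nan)
    count = np.zeros(lattice.n_oxygens, dtype=int)
    for b, (i, j) in enumerate(lattice.bond_pairs):
        o = int(i if donor[b] == 0 else j)
        direction = unit[b] if donor[b] == 0 else -unit[b]
        protons[o, count[o]] = lattice.oxygens[o] + R_OH * direction
        count[o] += 1
    if not (count == 2).all():
        bad = int((count != 2).sum())
        raise ProtonAssignmentError(f"{bad} oxygens ended up without exactly 2 protons")
    return replace(lattice, bond_donor=donor, protons=protons)


def ice_rule_defects(lattice: IceLattice) -> tuple[int, int]:
    """(rule-I defects, rule-II defects) of the current proton configuration.

    Rule II is structural here (one proton per directed bond), so the second
    count can only be nonzero if ``bond_donor`` is missing values; rule I
    counts oxygens whose donated-bond count differs from 2.
    """
    if lattice.bond_donor is None:
        raise ValueError("protons not assigned")
    out_deg = np.zeros(lattice.n_oxygens, dtype=int)
    i, j = lattice.bond_pairs.T
    np.add.at(out_deg, i[lattice.bond_donor == 0], 1)
    np.add.at(out_deg, j[lattice.bond_donor == 1], 1)
    deg = np.zeros(lattice.n_oxygens, dtype=int)
    np.add.at(deg, i, 1)
    np.add.at(deg, j, 1)
    interior = deg == 4
    rule1 = int((out_deg[interior] != 2).sum())
    return rule1, 0


def translation_period(
    points: np.ndarray,
    cell: np.ndarray,
    axis: np.ndarray,
    tol: float = 1e-5,
) -> float:
    """Smallest positive translation along ``axis`` mapping the set onto itself.

    Works on the periodically wrapped point set, so the measurement is
    independent of how the block was generated.  Candidate periods are the
    pair separations whose perpendicular component vanishes.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    pts = np.mod(points, cell)
    tree = cKDTree(pts, boxsize=cell)
    diffs = points[None, :, :] - points[:, None, :]
    para = diffs @ axis
    perp = np.linalg.norm(diffs - para[..., None] * axis, axis=-1)
    cand = np.unique(np.round(para[(perp < tol) & (para > tol)], 6))
    for t in sorted(cand):
        shifted = np.mod(pts + t * axis, cell)
        d, _ = tree.query(shifted, k=1)
        if np.max(d) < 10 * tol:
            return float(t)
    raise ValueError("no translation period found along the requested axis")
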