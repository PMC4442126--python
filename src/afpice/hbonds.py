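"""Geometric hydrogen-bond detection and ordered bridging-water analysis.

A hydrogen bond is recorded between a donor oxygen D (carrying hydrogen
H) and an acceptor oxygen A when the D-A distance is at most ``d_max``
(default 3.5 A) and the H-D-A angle is at most ``angle_max`` (default
30 degrees), both under the minimum-image convention.  This is the
standard geometric criterion used in MD analysis.

The ordered-water detector looks for the bridging waters characteristic
of the spruce budworm AFP bound state: water molecules that are not part
of the ice lattice yet are hydrogen-bonded simultaneously to prism-face
ice waters and to the hydroxyl groups of the ice-binding-surface
threonine residues.  "Fully coordinated" members carry at least two
hydrogen bonds to each side, i.e. a fully satisfied tetrahedral
arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["HydrogenBond", "OrderedWaterSet", "detect_hbonds", "detect_ordered_waters"]


@dataclass(frozen=True)
class HydrogenBond:
    donor: int
    acceptor: int
    hydrogen: int
    distance: float
    angle: float


def _min_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    box = np.asarray(box, float)
    out = vec.copy()
    for ax in range(3):
        if box[ax] > 0:
            out[..., ax] -= box[ax] * np.rint(out[..., ax] / box[ax])
    return out


def detect_hbonds(
    donor_o: np.ndarray,
    donor_h: np.ndarray,
    h_owner: np.ndarray,
    acceptor_o: np.ndarray,
    box: np.ndarray | None = None,
    d_max: float = 3.5,
    angle_max: float = 30.0,
    exclude_pairs: set[tuple[int, int]] | None = None,
) -> list[HydrogenBond]:
    """Geometric hydrogen bonds from donors (with hydrogens) to acceptors.

    Parameters
    ----------
    donor_o : (Nd, 3)
        Donor oxygen positions.
    donor_h : (Nh, 3)
        Hydrogen positions.
    h_owner : (Nh,)
        Index into ``donor_o`` of each hydrogen's parent oxygen.  Raises
        if a donor has no hydrogens to evaluate.
    acceptor_o : (Na, 3)
        Acceptor oxygen positions.
    exclude_pairs
        Optional (donor_index, acceptor_index) pairs to skip (e.g. an
        oxygen listed in both roles).
    """
    donor_o = np.asarray(donor_o, float)
    donor_h = np.asarray(donor_h, float)
    h_owner = np.asarray(h_owner, int)
    acceptor_o = np.asarray(acceptor_o, float)
    if len(donor_o) and len(donor_h) == 0:
        raise ValueError(
            "donors have no hydrogens; supply explicit hydrogen positions "
            "(no inference rule is applied)"
        )
    h_of: list[list[int]] = [[] for _ in range(len(donor_o))]
    for hi, oi in enumerate(h_owner):
        h_of[oi].append(hi)

    bonds: list[HydrogenBond] = []
    if len(donor_o) == 0 or len(acceptor_o) == 0:
        return bonds
    if box is not None:
        boxarr = np.asarray(box, float)
        tree = cKDTree(np.mod(acceptor_o, boxarr), boxsize=boxarr)
        neighbours = tree.query_ball_point(np.mod(donor_o, boxarr), d_max)
    else:
        tree = cKDTree(acceptor_o)
        neighbours = tree.query_ball_point(donor_o, d_max)
    cos_max = np.cos(np.deg2rad(angle_max))
    for di, acc in enumerate(neighbours):
        for ai in acc:
            if exclude_pairs and (di, ai) in exclude_pairs:
                continue
            da = _min_image(acceptor_o[ai] - donor_o[di], box)
            dist = float(np.linalg.norm(da))
            if dist < 1e-6 or dist > d_max:
                continue
            for hi in h_of[di]:
                dh = _min_image(donor_h[hi] - donor_o[di], box)
                cosang = float(da @ dh / (dist * np.linalg.norm(dh)))
                if cosang >= cos_max:
                    bonds.append(
                        HydrogenBond(
                            donor=di,
                            acceptor=ai,
                            hydrogen=hi,
                            distance=dist,
                            angle=float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))),
                        )
                    )
    return bonds


@dataclass
class OrderedWaterSet:
    """Bridging waters between the ice surface and the AFP threonine row.

    ``members`` indexes into the water-oxygen array handed to the
    detector.  Spacings are nearest-neighbour separations of the members
    along the crystallographic a-axis.  ``lattice_distances`` reports, per
    member, the distance to the nearest ideal bulk-ice lattice site (to
    show the bridging waters are structurally distinct from the ice), or
    None when no reference sites were supplied.
    """

    members: np.ndarray
    n_ice_bonds: np.ndarray
    n_ibs_bonds: np.ndarray
    fully_coordinated: np.ndarray
    spacings: np.ndarray
    mean_spacing: float | None
    lattice_distances: np.ndarray | None

    @property
    def n_members(self) -> int:
        return len(self.members)


def detect_ordered_waters(
    water_o: np.ndarray,
    water_h: np.ndarray,
    ice_mask: np.ndarray,
    ibs_o: np.ndarray,
    ibs_h: np.ndarray,
    box: np.ndarray | None = None,
    d_max: float = 3.5,
    angle_max: float = 30.0,
    a_axis: np.ndarray = (1.0, 0.0, 0.0),
    lattice_sites: np.ndarray | None = None,
) -> OrderedWaterSet:
    """Find liquid-labelled waters bridging ice and the AFP threonine row.

    Parameters
    ----------
    water_o : (N, 3)
        All water oxygens in the frame.
    water_h : (N, 2, 3)
        Their hydrogens.
    ice_mask : (N,) bool
        True for waters classified as ice.
    ibs_o, ibs_h : (M, 3)
        Threonine hydroxyl oxygen (OG1) and hydroxyl hydrogen (HG1)
        positions of the ice-binding surface.
    lattice_sites : optional (K, 3)
        Ideal bulk-ice lattice positions used to report how far each
        member sits from the nearest ideal site.

    A water qualifies as a member when it has at least one hydrogen bond
    (in either donor/acceptor direction) to an ice-labelled water and at
    least one to an IBS hydroxyl; members with >= 2 of each are flagged
    fully coordinated.
    """
    water_o = np.asarray(water_o, float)
    water_h = np.asarray(water_h, float)
    ice_mask = np.asarray(ice_mask, bool)
    ibs_o = np.asarray(ibs_o, float)
    ibs_h = np.asarray(ibs_h, float)
    if len(ibs_o) == 0:
        raise ValueError("empty ice-binding-surface hydroxyl set")

    n = len(water_o)
    flat_h = water_h.reshape(-1, 3)
    owner = np.repeat(np.arange(n), water_h.shape[1])

    n_ice = np.zeros(n, dtype=int)
    n_ibs = np.zeros(n, dtype=int)
    ice_idx = np.nonzero(ice_mask)[0]

    # water (donor) -> ice water (acceptor)
    for b in detect_hbonds(water_o, flat_h, owner, water_o[ice_idx], box, d_max, angle_max):
        if not ice_mask[b.donor]:
            n_ice[b.donor] += 1
    # ice water (donor) -> water (acceptor)
    ice_h = water_h[ice_idx].reshape(-1, 3)
    ice_owner = np.repeat(np.arange(len(ice_idx)), water_h.shape[1])
    for b in detect_hbonds(water_o[ice_idx], ice_h, ice_owner, water_o, box, d_max, angle_max):
        if not ice_mask[b.acceptor]:
            n_ice[b.acceptor] += 1
    # water (donor) -> IBS hydroxyl (acceptor)
    for b in detect_hbonds(water_o, flat_h, owner, ibs_o, box, d_max, angle_max):
        if not ice_mask[b.donor]:
            n_ibs[b.donor] += 1
    # IBS hydroxyl (donor) -> water (acceptor)
    ibs_owner = np.arange(len(ibs_o))
    for b in detect_hbonds(ibs_o, ibs_h, ibs_owner, water_o, box, d_max, angle_max):
        if not ice_mask[b.acceptor]:
            n_ibs[b.acceptor] += 1

    members = np.nonzero((n_ice >= 1) & (n_ibs >= 1) & ~ice_mask)[0]
    axis = np.asarray(a_axis, float)
    axis = axis / np.linalg.norm(axis)
    proj = water_o[members] @ axis
    order = np.argsort(proj)
    members = members[order]
    spacings = np.diff(np.sort(proj))
    mean_spacing = float(np.mean(spacings)) if len(spacings) else None

    lattice_distances = None
    if lattice_sites is not None and len(members):
        tree = cKDTree(np.asarray(lattice_sites, float))
        lattice_distances, _ = tree.query(water_o[members], k=1)

    return OrderedWaterSet(
        members=members,
        n_ice_bonds=n_ice[members],
        n_ibs_bonds=n_ibs[members],
        fully_coordinated=(n_ice[members] >= 2) & (n_ibs[members] >= 2),
        spacings=spacings,
        mean_spacing=mean_spacing,
        lattice_distances=lattice_distances,
    )
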