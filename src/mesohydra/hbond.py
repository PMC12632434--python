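"""Geometric hydrogen-bond counting and distance-resolved coordination profiles.

A hydrogen bond is declared between a donor heavy atom D (carrying an H)
and an acceptor heavy atom A when the D-A distance under the
minimum-image convention is at most ``r_cut`` (0.35 nm default) and the
H-D-A angle — measured at the donor, between the D->H and D->A vectors —
is at most ``angle_cut`` (30 degrees default).  This is the canonical
geometric criterion; both thresholds are configurable.

Per-water bond counts (a water participates in a bond as donor or
acceptor; water-water bonds count once for each partner) are binned by
the folded distance of the water oxygen from the membrane midplane to
give coordination profiles n_HB(z), from which the bulk-recovery
distance x_c and Arrhenius temperature dependence of the mean bond
count are extracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .thz import ArrheniusFit, arrhenius_fit

ROLES = ("water_O", "water_H", "lipid_donor_heavy",
         "lipid_acceptor_heavy", "lipid_H", "other")

#: Covalent O-H search radius used to attach hydrogens to their heavy atom (nm).
BOND_OH_NM = 0.125

_AXIS = {"x": 0, "y": 1, "z": 2}

__all__ = [
    "Frame",
    "HBRecord",
    "HBProfile",
    "find_hbonds",
    "per_water_counts",
    "hb_profile",
    "bulk_value",
    "bulk_recovery_distance",
    "hb_arrhenius",
]


@dataclass
class Frame:
    """One periodic coordinate frame (positions in nm)."""

    positions: np.ndarray           # (n, 3)
    roles: np.ndarray               # (n,) strings from ROLES
    molecule: np.ndarray            # (n,) integer molecule index
    box: np.ndarray                 # (3,) orthorhombic edge lengths
    temperature: float = 298.0
    membrane_normal: str = "z"
    z_mid: float | None = None      # midplane coordinate along the normal

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles)
        self.molecule = np.asarray(self.molecule, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if self.roles.shape != (n,) or self.molecule.shape != (n,):
            raise ValueError("roles and molecule must be length n")
        unknown = set(np.unique(self.roles)) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths")
        if self.membrane_normal not in _AXIS:
            raise ValueError("membrane_normal must be one of x, y, z")
        if self.z_mid is None:
            self.z_mid = float(self.box[_AXIS[self.membrane_normal]]) / 2.0
        self._check_waters()

    def _check_waters(self) -> None:
        o_mols = self.molecule[self.roles == "water_O"]
        h_mols = self.molecule[self.roles == "water_H"]
        uniq_o, o_counts = np.unique(o_mols, return_counts=True)
        if np.any(o_counts != 1):
            raise ValueError("a water molecule must have exactly one oxygen")
        uniq_h, h_counts = np.unique(h_mols, return_counts=True)
        ok = (len(uniq_h) == len(uniq_o) and np.array_equal(uniq_h, uniq_o)
              and np.all(h_counts == 2))
        if not ok:
            raise ValueError("every water molecule needs exactly 2 hydrogens")

    @property
    def normal_axis(self) -> int:
        return _AXIS[self.membrane_normal]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, box)."""
        return np.mod(self.positions, self.box)

    def water_molecules(self) -> np.ndarray:
        return np.unique(self.molecule[self.roles == "water_O"])

    def has_lipids(self) -> bool:
        return bool(np.any(np.isin(
            self.roles, ("lipid_donor_heavy", "lipid_acceptor_heavy", "lipid_H"))))


@dataclass(frozen=True)
class HBRecord:
    donor_molecule: int
    acceptor_molecule: int
    kind: str                   # "ww" or "wl"
    distance_nm: float
    angle_deg: float


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _attach_hydrogens(frame: Frame, donor_idx: np.ndarray,
                      h_idx: np.ndarray) -> np.ndarray:
    """Covalently bonded hydrogens per donor heavy atom, -1 padded.

    A hydrogen belongs to a donor when it shares the molecule and sits
    within BOND_OH_NM (minimum image).  Returns an (n_donor, k) index
    matrix into the frame's atoms.
    """
    pos, box = frame.positions, frame.box
    if len(h_idx) == 0 or len(donor_idx) == 0:
        return np.full((len(donor_idx), 1), -1, dtype=int)
    # candidate (donor, H) pairs from molecule identity
    d_mol = frame.molecule[donor_idx]
    h_mol = frame.molecule[h_idx]
    order = np.argsort(h_mol, kind="stable")
    h_sorted, h_mol_sorted = h_idx[order], h_mol[order]
    lo = np.searchsorted(h_mol_sorted, d_mol, side="left")
    hi = np.searchsorted(h_mol_sorted, d_mol, side="right")
    k_max = int(np.max(hi - lo)) if len(lo) else 0
    attached = np.full((len(donor_idx), max(k_max, 1)), -1, dtype=int)
    for col in range(k_max):
        take = lo + col < hi
        h_at = h_sorted[np.minimum(lo + col, len(h_sorted) - 1)]
        dv = _min_image(pos[h_at] - pos[donor_idx], box)
        near = np.linalg.norm(dv, axis=1) <= BOND_OH_NM
        sel = take & near
        attached[sel, col] = h_at[sel]
    return attached


def find_hbonds(frame: Frame, r_cut: float = 0.35,
                angle_cut: float = 30.0) -> list[HBRecord]:
    """Enumerate hydrogen bonds by the geometric distance/angle criterion.

    Donor-acceptor candidate pairs come from a periodic k-d tree
    neighbour query at ``r_cut``; the result is identical to an
    all-pairs search.  Water-water (ww) and water-lipid (wl) bonds are
    returned; lipid-lipid contacts are ignored.
    """
    if np.any(frame.box <= 2.0 * r_cut):
        raise ValueError("box too small for the minimum-image convention at r_cut")
    roles = frame.roles
    donor_heavy = np.flatnonzero((roles == "water_O") | (roles == "lipid_donor_heavy"))
    acceptor_heavy = np.flatnonzero(
        (roles == "water_O") | (roles == "lipid_acceptor_heavy")
        | (roles == "lipid_donor_heavy"))
    h_idx = np.flatnonzero((roles == "water_H") | (roles == "lipid_H"))
    heavy = np.unique(np.concatenate([donor_heavy, acceptor_heavy]))
    if len(heavy) == 0:
        return []
    attached = _attach_hydrogens(frame, donor_heavy, h_idx)

    wrapped = frame.wrapped()
    # cKDTree with a toroidal topology is the neighbour list
    tree = cKDTree(wrapped[heavy], boxsize=frame.box)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    if len(pairs) == 0:
        return []
    i = heavy[pairs[:, 0]]
    j = heavy[pairs[:, 1]]
    keep = frame.molecule[i] != frame.molecule[j]
    i, j = i[keep], j[keep]

    is_donor = np.zeros(len(frame.positions), dtype=bool)
    is_donor[donor_heavy] = True
    is_acceptor = np.zeros(len(frame.positions), dtype=bool)
    is_acceptor[acceptor_heavy] = True
    donor_row = np.full(len(frame.positions), -1, dtype=int)
    donor_row[donor_heavy] = np.arange(len(donor_heavy))

    cos_cut = math.cos(math.radians(angle_cut))
    pos, box = frame.positions, frame.box
    is_water_o = roles == "water_O"
    records: list[HBRecord] = []
    for d, acc in ((i, j), (j, i)):
        mask = is_donor[d] & is_acceptor[acc]
        d, acc = d[mask], acc[mask]
        if len(d) == 0:
            continue
        dv = _min_image(pos[acc] - pos[d], box)
        dist = np.linalg.norm(dv, axis=1)
        ok = (dist <= r_cut) & (dist > 0.0)
        d, acc, dv, dist = d[ok], acc[ok], dv[ok], dist[ok]
        hmat = attached[donor_row[d]]  # (m, k) H indices, -1 padded
        for col in range(hmat.shape[1]):
            h = hmat[:, col]
            valid = h >= 0
            if not np.any(valid):
                continue
            hv = _min_image(pos[np.maximum(h, 0)] - pos[d], box)
            nh = np.linalg.norm(hv, axis=1)
            valid &= nh > 0.0
            cosang = np.einsum("ij,ij->i", hv, dv) / np.where(
                nh * dist > 0, nh * dist, 1.0)
            cosang = np.clip(cosang, -1.0, 1.0)
            hit = valid & (cosang >= cos_cut)
            for k in np.flatnonzero(hit):
                kind = "ww" if is_water_o[d[k]] and is_water_o[acc[k]] else "wl"
                records.append(HBRecord(
                    donor_molecule=int(frame.molecule[d[k]]),
                    acceptor_molecule=int(frame.molecule[acc[k]]),
                    kind=kind, distance_nm=float(dist[k]),
                    angle_deg=math.degrees(math.acos(float(cosang[k]))),
                ))
    return records


def _per_water_arrays(frame: Frame,
                      records: list[HBRecord]) -> tuple[np.ndarray, np.ndarray,
                                                        np.ndarray]:
    """(water molecule ids, ww counts, wl counts), aligned and sorted by id."""
    waters = frame.water_molecules()
    ww = np.zeros(len(waters))
    wl = np.zeros(len(waters))
    if records:
        mols = np.array([[r.donor_molecule, r.acceptor_molecule] for r in records])
        is_ww = np.array([r.kind == "ww" for r in records])
        for side in (0, 1):
            pos = np.searchsorted(waters, mols[:, side])
            pos_ok = (pos < len(waters)) & (waters[np.minimum(pos, len(waters) - 1)]
                                            == mols[:, side])
            np.add.at(ww, pos[pos_ok & is_ww], 1.0)
            np.add.at(wl, pos[pos_ok & ~is_ww], 1.0)
    return waters, ww, wl


def per_water_counts(frame: Frame, records: list[HBRecord]) -> dict[int, dict[str, float]]:
    """Bond counts per water molecule, split into ww and wl contributions."""
    waters, ww, wl = _per_water_arrays(frame, records)
    return {int(m): {"ww": float(a), "wl": float(b)}
            for m, a, b in zip(waters, ww, wl)}


@dataclass
class HBProfile:
    """Distance-resolved mean hydrogen-bond counts per water molecule."""

    bin_centers: np.ndarray
    n_HB_total: np.ndarray
    n_HB_ww: np.ndarray
    n_HB_wl: np.ndarray
    water_counts: np.ndarray
    temperature: float
    mean_total: float                     # frame-wide mean n_HB per water
    n_HB_bulk: float = float("nan")
    x_c: float = float("nan")
    x_c_reached: bool = False
    empty_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_nm": self.bin_centers, "n_total": self.n_HB_total,
            "n_ww": self.n_HB_ww, "n_wl": self.n_HB_wl,
            "count": self.water_counts,
        })


def _water_distances(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    """(molecule ids, folded |z_O - z_mid|) for every water in a frame."""
    ax = frame.normal_axis
    L = frame.box[ax]
    o_idx = np.flatnonzero(frame.roles == "water_O")
    z = frame.positions[o_idx, ax]
    dz = np.abs(z - frame.z_mid)
    dz = np.minimum(np.mod(dz, L), L - np.mod(dz, L))
    return frame.molecule[o_idx], dz


def hb_profile(frames: list[Frame], bin_width: float = 0.1,
               r_cut: float = 0.35, angle_cut: float = 30.0) -> HBProfile:
    """Average per-water bond counts binned by distance from the midplane.

    Each water is assigned to a bin by the folded |z_O - z_mid| along
    the membrane normal; means are taken over all waters of all frames.
    Empty bins are reported with count 0 and NaN mean, not dropped.
    """
    if not frames:
        raise ValueError("at least one frame required")
    half = max(float(f.box[f.normal_axis]) / 2.0 for f in frames)
    n_bins = int(math.ceil(half / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    sums = np.zeros((3, n_bins))
    counts = np.zeros(n_bins)
    total_sum = 0.0
    total_n = 0
    for frame in frames:
        records = find_hbonds(frame, r_cut=r_cut, angle_cut=angle_cut)
        waters, ww, wl = _per_water_arrays(frame, records)
        mols, dz = _water_distances(frame)
        # align per-water counts (sorted by molecule id) with oxygen order
        pos = np.searchsorted(waters, mols)
        tot = ww[pos] + wl[pos]
        idx = np.minimum((dz / bin_width).astype(int), n_bins - 1)
        np.add.at(sums[0], idx, tot)
        np.add.at(sums[1], idx, ww[pos])
        np.add.at(sums[2], idx, wl[pos])
        np.add.at(counts, idx, 1.0)
        total_sum += float(tot.sum())
        total_n += len(mols)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    empty = np.flatnonzero(counts == 0)
    return HBProfile(
        bin_centers=centers, n_HB_total=means[0], n_HB_ww=means[1],
        n_HB_wl=means[2], water_counts=counts,
        temperature=frames[0].temperature,
        mean_total=total_sum / total_n if total_n else float("nan"),
        empty_bins=empty,
    )


def bulk_value(frames: list[Frame], r_cut: float = 0.35,
               angle_cut: float = 30.0) -> float:
    """Mean hydrogen bonds per water over pure-water reference frames."""
    if not frames:
        raise ValueError("at least one frame required")
    total, n = 0.0, 0
    for frame in frames:
        if frame.has_lipids():
            raise ValueError("bulk reference frames must contain only water")
        records = find_hbonds(frame, r_cut=r_cut, angle_cut=angle_cut)
        _, ww, wl = _per_water_arrays(frame, records)
        total += float(ww.sum() + wl.sum())
        n += len(ww)
    return total / n


def bulk_recovery_distance(profile: HBProfile, tol: float = 0.02) -> HBProfile:
    """Smallest bin center beyond which coordination stays bulk-like.

    x_c is the smallest occupied bin center whose total mean — and that
    of every farther occupied bin — lies within ``tol`` (relative) of
    the bulk reference.  When no such bin exists the profile is flagged
    unreached (x_c = NaN).
    """
    if not np.isfinite(profile.n_HB_bulk) or profile.n_HB_bulk <= 0:
        raise ValueError("profile needs a positive bulk reference (set n_HB_bulk)")
    occupied = profile.water_counts > 0
    ok = np.zeros(len(profile.bin_centers), dtype=bool)
    ok[occupied] = (np.abs(profile.n_HB_total[occupied] - profile.n_HB_bulk)
                    / profile.n_HB_bulk) < tol
    x_c, reached = float("nan"), False
    # scan from far side: all farther occupied bins must also be bulk-like
    good_tail = True
    for i in range(len(ok) - 1, -1, -1):
        if not occupied[i]:
            continue
        if not ok[i]:
            break
        if good_tail:
            x_c, reached = float(profile.bin_centers[i]), True
    profile.x_c = x_c
    profile.x_c_reached = reached
    return profile


def hb_arrhenius(profiles: list[HBProfile], label: str = "n_HB") -> ArrheniusFit:
    """Arrhenius fit of the frame-wide mean bond count over temperature."""
    if len(profiles) < 3:
        raise ValueError("Arrhenius fit requires profiles at >= 3 temperatures")
    values = np.array([p.mean_total for p in profiles])
    T = np.array([p.temperature for p in profiles])
    return arrhenius_fit(values, T, label=label)
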