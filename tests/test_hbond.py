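"""Geometric hydrogen-bond counting, profiles and bulk-recovery distance."""

import math

import numpy as np
import pytest

from conftest import build_frame, random_water_frame
from mesohydra import hbond
from mesohydra.hbond import Frame, HBProfile
from mesohydra.thz import GAS_CONSTANT


def brute_force_hbonds(frame, r_cut=0.35, angle_cut=30.0):
    """O(n^2) all-pairs oracle for the geometric criterion.

    Returns the HB set as tuples (donor_mol, acceptor_mol, kind).
    """
    pos, box, roles, mols = (frame.positions, frame.box, frame.roles,
                             frame.molecule)

    def mi(d):
        return d - box * np.round(d / box)

    donors = [i for i in range(len(pos))
              if roles[i] in ("water_O", "lipid_donor_heavy")]
    acceptors = [i for i in range(len(pos))
                 if roles[i] in ("water_O", "lipid_acceptor_heavy",
                                 "lipid_donor_heavy")]
    hydrogens = [i for i in range(len(pos)) if roles[i] in ("water_H", "lipid_H")]
    found = []
    for d in donors:
        hs = [h for h in hydrogens
              if mols[h] == mols[d] and np.linalg.norm(mi(pos[h] - pos[d])) <= 0.125]
        for a in acceptors:
            if mols[a] == mols[d]:
                continue
            dv = mi(pos[a] - pos[d])
            dist = np.linalg.norm(dv)
            if dist > r_cut or dist == 0.0:
                continue
            for h in hs:
                hv = mi(pos[h] - pos[d])
                cosang = np.dot(hv, dv) / (np.linalg.norm(hv) * dist)
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) <= angle_cut:
                    kind = ("ww" if roles[d] == "water_O" and roles[a] == "water_O"
                            else "wl")
                    found.append((int(mols[d]), int(mols[a]), kind))
    return sorted(found)


def as_tuples(records):
    return sorted((r.donor_molecule, r.acceptor_molecule, r.kind)
                  for r in records)


class TestFindHbonds:
    def test_waters_beyond_cutoff(self):
        frame = build_frame([
            ((1.0, 1.0, 1.0), (0.1, 0, 0), (0, 0.1, 0)),
            ((1.5, 1.0, 1.0), (0.1, 0, 0), (0, 0.1, 0)),
        ])
        assert hbond.find_hbonds(frame) == []

    def test_ideal_linear_dimer(self):
        # donor H on the O-O axis, O-O = 0.28 nm: exactly one w-w bond
        frame = build_frame([
            ((1.0, 1.0, 1.0), (0.1, 0, 0), (0, 0, 0.1)),
            ((1.28, 1.0, 1.0), (0.1, 0, 0), (0, 0, 0.1)),
        ])
        records = hbond.find_hbonds(frame)
        assert len(records) == 1
        assert records[0].kind == "ww"
        assert records[0].distance_nm == pytest.approx(0.28)
        assert records[0].angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_angle_just_beyond_cutoff_rejected(self):
        theta = math.radians(31.0)
        frame = build_frame([
            ((1.0, 1.0, 1.0), (0.1 * math.cos(theta), 0.1 * math.sin(theta), 0),
             (0, 0, 0.1)),
            ((1.28, 1.0, 1.0), (0.1, 0, 0), (0, 0, 0.1)),
        ])
        assert hbond.find_hbonds(frame) == []

    def test_bond_across_periodic_boundary(self):
        frame = build_frame([
            ((0.05, 1.0, 1.0), (-0.1, 0, 0), (0, 0, 0.1)),
            ((1.85, 1.0, 1.0), (0, 0.1, 0), (0, 0, 0.1)),
        ], box=(2.0, 2.0, 2.0))
        records = hbond.find_hbonds(frame)
        assert len(records) == 1
        assert records[0].distance_nm == pytest.approx(0.2)

    def test_small_box_rejected(self):
        frame = build_frame([((0.3, 0.3, 0.3), (0.1, 0, 0), (0, 0.1, 0))],
                            box=(0.6, 0.6, 0.6))
        with pytest.raises(ValueError):
            hbond.find_hbonds(frame)

    def test_neighbor_list_equals_brute_force(self, rng):
        for k in range(50):
            frame = random_water_frame(
                rng, n_water=int(rng.integers(20, 120)),
                box=float(rng.uniform(1.5, 3.0)),
                n_lipid_sites=int(rng.integers(0, 10)))
            assert as_tuples(hbond.find_hbonds(frame)) == brute_force_hbonds(frame)

    def test_criterion_monotonicity(self, rng):
        for _ in range(10):
            frame = random_water_frame(rng, n_water=60, box=2.0)
            base = set(as_tuples(hbond.find_hbonds(frame)))
            wider_r = set(as_tuples(hbond.find_hbonds(frame, r_cut=0.45)))
            wider_a = set(as_tuples(hbond.find_hbonds(frame, angle_cut=45.0)))
            assert base <= wider_r
            assert base <= wider_a


class TestBulkValue:
    def test_isolated_waters_have_no_bonds(self):
        frame = build_frame([
            ((0.5, 0.5, 0.5), (0.1, 0, 0), (0, 0.1, 0)),
            ((2.5, 2.5, 2.5), (0.1, 0, 0), (0, 0.1, 0)),
        ])
        assert hbond.bulk_value([frame]) == 0.0

    def test_square_lattice_coordination_of_four(self):
        # central water donates 2 and accepts 2 on a plus-shaped motif;
        # replicate so every water is equivalent under periodicity
        d = 0.3
        waters = []
        n = 4
        for i in range(n):
            for j in range(n):
                x, y = i * d, j * d
                # alternate donor orientation along +x / +y checkerboard
                waters.append(((x, y, 0.6), (0.1, 0, 0), (0, 0.1, 0)))
        frame = build_frame(waters, box=(n * d, n * d, 1.2))
        per_mol = hbond.per_water_counts(frame, hbond.find_hbonds(frame))
        # every water donates 2 (both H at 0 deg to +x/+y neighbours) and
        # accepts 2 (from -x and -y neighbours): 4 bonds per molecule
        assert all(c["ww"] == 4.0 for c in per_mol.values())
        assert hbond.bulk_value([frame]) == 4.0

    def test_lipid_contamination_rejected(self):
        frame = build_frame(
            [((0.5, 0.5, 0.5), (0.1, 0, 0), (0, 0.1, 0))],
            lipids=[((1.5, 1.5, 1.5), "lipid_donor_heavy"),
                    ((1.6, 1.5, 1.5), "lipid_H")])
        with pytest.raises(ValueError):
            hbond.bulk_value([frame])

    def test_random_box_equals_oracle_mean(self, rng):
        frame = random_water_frame(rng, n_water=80, box=2.0)
        oracle = brute_force_hbonds(frame)
        ends = sum(1 for d, a, k in oracle for m in (d, a))
        assert hbond.bulk_value([frame]) == pytest.approx(
            ends / len(frame.water_molecules()))


class TestProfile:
    def _uniform_frame(self, z, n=20, box=5.0):
        waters = [((0.25 + 0.6 * k % box, 0.25 + 0.6 * ((0.6 * k) // box), z),
                   (0.1, 0, 0), (0, 0.1, 0)) for k in range(n)]
        return build_frame(waters, box=(box, box, box))

    def test_single_z_gives_single_occupied_bin(self):
        frame = self._uniform_frame(z=1.0)
        profile = hbond.hb_profile([frame])
        occupied = profile.water_counts > 0
        assert occupied.sum() == 1
        k = np.flatnonzero(occupied)[0]
        assert profile.n_HB_total[k] == pytest.approx(profile.mean_total)

    def test_two_identical_frames_idempotent(self):
        frame = self._uniform_frame(z=1.0)
        p1 = hbond.hb_profile([frame])
        p2 = hbond.hb_profile([frame, frame])
        assert np.allclose(p1.water_counts * 2,
                           p2.water_counts)
        valid = p1.water_counts > 0
        assert np.allclose(p1.n_HB_total[valid], p2.n_HB_total[valid])

    def test_bookkeeping_conservation(self, rng):
        # sum over bins of count*mean equals total HB-ends on waters
        frame = random_water_frame(rng, n_water=100, box=2.5)
        profile = hbond.hb_profile([frame])
        records = hbond.find_hbonds(frame)
        waters = set(int(m) for m in frame.water_molecules())
        ends = sum((r.donor_molecule in waters) + (r.acceptor_molecule in waters)
                   for r in records)
        valid = profile.water_counts > 0
        total = np.sum(profile.water_counts[valid] * profile.n_HB_total[valid])
        assert total == pytest.approx(ends)

    def test_empty_bins_flagged_not_dropped(self):
        frame = self._uniform_frame(z=1.0)
        profile = hbond.hb_profile([frame])
        assert len(profile.empty_bins) > 0
        assert np.isnan(profile.n_HB_total[profile.empty_bins]).all()


class TestBulkRecovery:
    def _profile(self, values, counts=None, bulk=1.0):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return HBProfile(
            bin_centers=(np.arange(n) + 0.5) * 0.1,
            n_HB_total=values, n_HB_ww=values, n_HB_wl=np.zeros(n),
            water_counts=np.full(n, 100.0) if counts is None else counts,
            temperature=308.0, mean_total=float(np.nanmean(values)),
            n_HB_bulk=bulk)

    def test_bulk_everywhere_returns_first_bin(self):
        profile = self._profile(np.ones(10))
        hbond.bulk_recovery_distance(profile)
        assert profile.x_c == pytest.approx(0.05)
        assert profile.x_c_reached

    def test_ramp_recovers_at_expected_bin(self):
        values = np.concatenate([np.full(24, 0.9), np.ones(11)])
        profile = self._profile(values)
        hbond.bulk_recovery_distance(profile)
        assert profile.x_c == pytest.approx(2.45)

    def test_never_within_tolerance_flagged_unreached(self):
        profile = self._profile(np.full(10, 0.5))
        hbond.bulk_recovery_distance(profile)
        assert not profile.x_c_reached
        assert np.isnan(profile.x_c)

    def test_missing_bulk_reference_rejected(self):
        profile = self._profile(np.ones(5), bulk=float("nan"))
        with pytest.raises(ValueError):
            hbond.bulk_recovery_distance(profile)


class TestHBArrhenius:
    def _profile_with_mean(self, mean, T):
        return HBProfile(
            bin_centers=np.array([0.05]), n_HB_total=np.array([mean]),
            n_HB_ww=np.array([mean]), n_HB_wl=np.array([0.0]),
            water_counts=np.array([10.0]), temperature=T, mean_total=mean)

    def test_constant_count_gives_zero_energy(self):
        profiles = [self._profile_with_mean(3.3, T) for T in (308.0, 318.0, 328.0)]
        assert hbond.hb_arrhenius(profiles).E_a_kJ_mol == 0.0

    def test_exact_arrhenius_count_series(self):
        T = np.arange(308.0, 339.0, 5.0)
        profiles = [self._profile_with_mean(
            0.4 * math.exp(1480.0 / (GAS_CONSTANT * t)), t) for t in T]
        fit = hbond.hb_arrhenius(profiles)
        assert fit.E_a_kJ_mol == pytest.approx(1.480, abs=1e-9)

    def test_requires_three_temperatures(self):
        profiles = [self._profile_with_mean(3.0, T) for T in (308.0, 318.0)]
        with pytest.raises(ValueError):
            hbond.hb_arrhenius(profiles)
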