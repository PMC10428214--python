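import math

import numpy as np
import pytest

from _oracles import brute_force_hbonds
from conftest import make_atom, make_triplet_structure
from trajnet import hbonds
from trajnet.errors import SpecError, TopologyError
from trajnet.hbonds import (
    FingerprintConfig,
    HBondCriteria,
    HBondKey,
    OccupancyTable,
    detect_hbonds_frame,
    occupancy_fingerprint,
    occupancy_table,
    residue_contact_barcode,
)
from trajnet.structures_io import Structure, Trajectory
from trajnet.synthetic import HBondSeriesSpec, make_hbond_trajectory

CRIT = HBondCriteria()


def triplet_coords(da_distance, angle_dev_deg=0.0):
    """Donor at origin, H at 1 Å along x, acceptor placed so the D–H···A
    angle deviates from linearity by exactly angle_dev_deg."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = math.radians(angle_dev_deg)
    direction = np.array([math.cos(theta), math.sin(theta), 0.0])
    a = h + (da_distance - 1.0) * direction
    return np.stack([d, h, a])


class TestDetection:
    def test_collinear_at_3_angstrom_is_bond(self):
        s = make_triplet_structure((0, 0, 0), (1, 0, 0), (3, 0, 0))
        found = detect_hbonds_frame(s.coords, s, CRIT)
        assert found == {HBondKey(donor=("A:1", "N"), acceptor=("A:2", "O"))}

    def test_collinear_at_3p3_angstrom_no_bond(self):
        s = make_triplet_structure((0, 0, 0), (1, 0, 0), (3.3, 0, 0))
        assert detect_hbonds_frame(s.coords, s, CRIT) == set()

    def test_angle_cutoff(self):
        s = make_triplet_structure((0, 0, 0), (1, 0, 0), (3, 0, 0))
        ok = triplet_coords(3.0, angle_dev_deg=15.0)
        bad = triplet_coords(3.0, angle_dev_deg=30.0)
        assert len(detect_hbonds_frame(ok, s, CRIT)) == 1
        assert detect_hbonds_frame(bad, s, CRIT) == set()

    def test_no_hydrogens_is_explicit_error(self):
        s = Structure([
            make_atom(1, "N", "DON", "A", 1, "N", (0, 0, 0)),
            make_atom(2, "O", "ACC", "A", 2, "O", (3, 0, 0)),
        ])
        with pytest.raises(TopologyError, match="hydrogen"):
            detect_hbonds_frame(s.coords, s, CRIT)

    def test_intra_residue_pairs_excluded(self):
        s = Structure([
            make_atom(1, "N", "ASN", "A", 1, "N", (0, 0, 0)),
            make_atom(2, "H", "ASN", "A", 1, "H", (1, 0, 0)),
            make_atom(3, "OD1", "ASN", "A", 1, "O", (3, 0, 0)),
        ])
        assert detect_hbonds_frame(s.coords, s, CRIT) == set()

    def test_brute_force_oracle_500_random_triplets(self, rng):
        s = make_triplet_structure((0, 0, 0), (1, 0, 0), (3, 0, 0))
        for _ in range(500):
            d = np.zeros(3)
            h_dir = rng.normal(size=3)
            h = d + rng.uniform(0.8, 1.4) * h_dir / np.linalg.norm(h_dir)
            a_dir = rng.normal(size=3)
            a = d + rng.uniform(2.0, 4.5) * a_dir / np.linalg.norm(a_dir)
            coords = np.stack([d, h, a])
            fast = detect_hbonds_frame(coords, s, CRIT)
            slow = brute_force_hbonds(coords, s.atoms, CRIT.max_da_distance,
                                      CRIT.max_angle_deviation)
            assert {(k.donor, k.acceptor) for k in fast} == slow

    def test_rotation_translation_invariance(self, rng):
        spec = HBondSeriesSpec(occupancies=[0.5, 0.8], n_frames=20, seed=2)
        traj, _, _ = make_hbond_trajectory(spec)
        for f in range(traj.n_frames):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            shift = rng.uniform(-50, 50, 3)
            moved = traj.frames[f] @ rot.T + shift
            assert detect_hbonds_frame(moved, traj.topology, CRIT) == \
                detect_hbonds_frame(traj.frames[f], traj.topology, CRIT)

    def test_donor_angle_convention_switch(self):
        crit = HBondCriteria(angle_convention="donor")
        # D->H along x, A 15° off the D->A... off the D->H axis
        coords = np.stack([
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
            [3.0 * math.cos(math.radians(15)), 3.0 * math.sin(math.radians(15)), 0.0],
        ])
        s = make_triplet_structure((0, 0, 0), (1, 0, 0), (3, 0, 0))
        assert len(detect_hbonds_frame(coords, s, crit)) == 1
        far = np.stack([
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
            [3.0 * math.cos(math.radians(25)), 3.0 * math.sin(math.radians(25)), 0.0],
        ])
        assert detect_hbonds_frame(far, s, crit) == set()


def _two_state_trajectory(bonded_frames, n_frames=10):
    """One triplet; bonded geometry on the given frame indices."""
    s = make_triplet_structure((0, 0, 0), (1, 0, 0), (2.9, 0, 0))
    frames = np.empty((n_frames, 3, 3))
    for f in range(n_frames):
        da = 2.9 if f in bonded_frames else 4.5
        frames[f] = [[0, 0, 0], [1, 0, 0], [da, 0, 0]]
    return Trajectory(s, frames)


class TestOccupancyTable:
    def test_always_bonded_is_one(self):
        traj = _two_state_trajectory(set(range(10)))
        table = occupancy_table(traj, CRIT, n_chunks=5)
        assert list(table.entries.values()) == [1.0]

    def test_half_bonded_is_half(self):
        traj = _two_state_trajectory({0, 1, 2, 3, 4})
        table = occupancy_table(traj, CRIT, n_chunks=5)
        assert list(table.entries.values()) == [0.5]

    def test_chunk_mean_equals_global(self):
        spec = HBondSeriesSpec(occupancies=[0.6, 0.3], n_frames=1000, seed=5)
        traj, _, _ = make_hbond_trajectory(spec)
        table = occupancy_table(traj, CRIT, n_chunks=5)
        for key, occ in table.entries.items():
            assert abs(np.mean(table.chunk_occupancies[key]) - occ) < 1e-12

    def test_markov_recovery(self):
        spec = HBondSeriesSpec(occupancies=[0.7], n_frames=2000, seed=8)
        traj, _, states = make_hbond_trajectory(spec)
        table = occupancy_table(traj, CRIT, n_chunks=5)
        occ = next(iter(table.entries.values()))
        assert occ == pytest.approx(states.mean(), abs=1e-12)

    def test_fewer_frames_than_chunks_rejected(self):
        traj = _two_state_trajectory({0}, n_frames=3)
        with pytest.raises(SpecError):
            occupancy_table(traj, CRIT, n_chunks=5)

    def test_equilibration_discard_uses_times(self):
        traj = _two_state_trajectory(set(range(5)), n_frames=10)
        traj.frame_times = list(np.arange(10) * 2.0)  # 0..18 ns
        table = occupancy_table(traj, CRIT, n_chunks=5)
        # 10 ns discard keeps frames at t >= 10 ns (indices 5..9, all broken)
        assert table.n_frames == 5
        assert table.entries == {}


class TestBarcode:
    def test_two_bonds_same_pair_count_once(self):
        # donor residue with two hydrogens pointing at two acceptor oxygens
        s = Structure([
            make_atom(1, "N1", "DON", "A", 1, "N", (0, 0, 0)),
            make_atom(2, "H1", "DON", "A", 1, "H", (1, 0, 0)),
            make_atom(3, "N2", "DON", "A", 1, "N", (0, 5, 0)),
            make_atom(4, "H2", "DON", "A", 1, "H", (1, 5, 0)),
            make_atom(5, "O1", "ACC", "A", 2, "O", (3, 0, 0)),
            make_atom(6, "O2", "ACC", "A", 2, "O", (3, 5, 0)),
        ])
        traj = Trajectory(s, s.coords[None])
        bonds = hbonds.detect_hbonds_frame(traj.frames[0], s, CRIT)
        assert len(bonds) == 2
        barcode = residue_contact_barcode(traj, "A:1", "A:2", CRIT)
        assert barcode.tolist() == [1]

    def test_no_contact_all_zero(self):
        spec = HBondSeriesSpec(occupancies=[0.0], n_frames=20)
        traj, _, _ = make_hbond_trajectory(spec)
        barcode = residue_contact_barcode(traj, "A:1", "A:2", CRIT)
        assert barcode.tolist() == [0] * 20

    def test_unknown_residue_rejected(self):
        spec = HBondSeriesSpec(occupancies=[0.5], n_frames=5)
        traj, _, _ = make_hbond_trajectory(spec)
        with pytest.raises(SpecError, match="Z:9"):
            residue_contact_barcode(traj, "A:1", "Z:9", CRIT)

    def test_barcode_mean_matches_pair_occupancy(self):
        spec = HBondSeriesSpec(occupancies=[0.65], n_frames=400, seed=4)
        traj, _, _ = make_hbond_trajectory(spec)
        table = occupancy_table(traj, CRIT, n_chunks=5)
        barcode = residue_contact_barcode(traj, "A:1", "A:2", CRIT)
        pair_occ = sum(
            occ for key, occ in table.entries.items()
            if {key.donor[0], key.acceptor[0]} == {"A:1", "A:2"}
        )
        assert barcode.mean() == pytest.approx(pair_occ, abs=1e-12)


def _table(entries, chunks=None, n_chunks=5, n_frames=100):
    chunks = chunks or {k: [v] * n_chunks for k, v in entries.items()}
    return OccupancyTable(dict(entries), dict(chunks), n_frames, n_chunks)


def _key(i):
    return HBondKey(donor=(f"A:{2 * i + 1}", "N"), acceptor=(f"A:{2 * i + 2}", "O"))


class TestFingerprint:
    def test_self_fingerprint_empty_selection(self):
        spec = HBondSeriesSpec(occupancies=[0.5, 0.9], mean_dwell_frames=10.0,
                               n_frames=500, seed=3)
        traj, _, _ = make_hbond_trajectory(spec)
        table = occupancy_table(traj, CRIT, n_chunks=5)
        entries, sigma = occupancy_fingerprint(table, table)
        assert sigma == 0.0
        assert all(not e.selected for e in entries)

    def test_planted_shift_is_unique_selection(self):
        base = [0.8, 0.55, 0.35, 0.6, 0.75, 0.5, 0.25, 0.65, 0.45, 0.7,
                0.3, 0.55, 0.4, 0.6, 0.5, 0.35, 0.65, 0.45, 0.7]
        ref_spec = HBondSeriesSpec(occupancies=[0.9] + base,
                                   mean_dwell_frames=10.0, n_frames=2000,
                                   seed=21)
        alt_spec = HBondSeriesSpec(occupancies=[0.5] + base,
                                   mean_dwell_frames=10.0, n_frames=2000,
                                   seed=22)
        ref_traj, _, _ = make_hbond_trajectory(ref_spec)
        alt_traj, _, _ = make_hbond_trajectory(alt_spec)
        ref = occupancy_table(ref_traj, CRIT, n_chunks=5)
        alt = occupancy_table(alt_traj, CRIT, n_chunks=5)
        entries, sigma = occupancy_fingerprint(ref, alt)
        selected = [e for e in entries if e.selected]
        assert len(selected) == 1
        assert selected[0].key == _key(0)
        assert selected[0].direction == "decrease"
        assert sigma > 0

    def test_direction_labels_carry_sign(self):
        n = 30
        ref = {_key(i): 0.5 for i in range(n)}
        alt = dict(ref)
        alt[_key(0)] = 0.95   # increase
        alt[_key(1)] = 0.05   # decrease
        entries, _ = occupancy_fingerprint(_table(ref), _table(alt))
        by_key = {e.key: e for e in entries}
        assert by_key[_key(0)].selected
        assert by_key[_key(0)].direction == "increase"
        assert by_key[_key(1)].selected
        assert by_key[_key(1)].direction == "decrease"

    def test_swap_negates_deltas(self):
        ref = {_key(i): v for i, v in enumerate([0.2, 0.5, 0.9])}
        alt = {_key(i): v for i, v in enumerate([0.4, 0.5, 0.6])}
        fwd, s1 = occupancy_fingerprint(_table(ref), _table(alt))
        rev, s2 = occupancy_fingerprint(_table(alt), _table(ref))
        assert s1 == pytest.approx(s2)
        fwd_map = {e.key: e.delta for e in fwd}
        rev_map = {e.key: e.delta for e in rev}
        for k in fwd_map:
            assert fwd_map[k] == pytest.approx(-rev_map[k])

    def test_missing_bond_counts_as_zero_occupancy(self):
        n = 30
        ref = {_key(i): 0.5 for i in range(n)}
        alt = {k: v for k, v in ref.items() if k != _key(0)}
        entries, _ = occupancy_fingerprint(_table(ref), _table(alt))
        by_key = {e.key: e for e in entries}
        assert by_key[_key(0)].delta == pytest.approx(-50.0)

    def test_chunk_instability_blocks_selection(self):
        n = 30
        ref = {_key(i): 0.5 for i in range(n)}
        alt = dict(ref)
        alt[_key(0)] = 0.95
        chunks_alt = {k: [v] * 5 for k, v in alt.items()}
        # same net shift but wildly scattered chunks -> chunk SD above 2σ
        chunks_alt[_key(0)] = [1.0, 0.0, 1.0, 0.75, 1.0]
        entries, _ = occupancy_fingerprint(
            _table(ref), _table(alt, chunks=chunks_alt))
        by_key = {e.key: e for e in entries}
        assert not by_key[_key(0)].selected

    def test_chunk_count_mismatch_rejected(self):
        ref = _table({_key(0): 0.5}, n_chunks=5)
        alt = _table({_key(0): 0.5}, n_chunks=4)
        with pytest.raises(SpecError, match="chunk"):
            occupancy_fingerprint(ref, alt)

    def test_sorted_by_abs_delta_descending(self):
        ref = {_key(i): 0.5 for i in range(4)}
        alt = {_key(0): 0.6, _key(1): 0.1, _key(2): 0.8, _key(3): 0.5}
        entries, _ = occupancy_fingerprint(_table(ref), _table(alt))
        deltas = [abs(e.delta) for e in entries]
        assert deltas == sorted(deltas, reverse=True)

    def test_absolute_point_threshold(self):
        cfg = FingerprintConfig()
        assert cfg.min_abs_difference == 20.0
        assert cfg.sigma_multiplier_select == 3.0
        assert cfg.sigma_multiplier_stability == 2.0
        assert cfg.n_chunks == 5
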