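"""Contact census, classification, maps, bridging waters, H-bond geometry."""

import numpy as np
import pytest

from ratchetpath.contacts import (
    bridging_waters, candidate_contacts, classify, contact_map, hbond_stats,
    water_bin_label,
)
from ratchetpath.io_model import Atom, Topology, Trajectory
from ratchetpath.toysim import ContactPlanEntry, synth_contact_trajectory


def pair_topology(n_extra_waters=0):
    atoms = [
        Atom(1, "N7", "N", 14.0, 200, "LIG"),
        Atom(2, "CA", "C", 12.0, 5, "GLU"),
    ]
    for w in range(n_extra_waters):
        atoms.append(Atom(3 + w, "O", "O", 16.0, 300 + w, "HOH"))
    return Topology(atoms=atoms, groups={
        "ligand": (0,), "protein": (1,), "core": (0,),
        "solvent": tuple(range(2, 2 + n_extra_waters))})


def traj_with_distances(distances, topology=None):
    topo = topology or pair_topology()
    frames = np.zeros((len(distances), topo.n_atoms, 3))
    frames[:, 1, 0] = distances
    return Trajectory(topology=topo, frames=frames, dt=1.0)


def brute_force_census(trajectories, ligand, protein, cutoff=4.0,
                       min_freq=0.5):
    """Independent oracle: explicit per-frame, per-pair loops."""
    out = {}
    for li in ligand:
        for pi in protein:
            freqs, dists = [], []
            for traj in trajectories:
                hits = 0
                for frame in traj.frames:
                    d = float(np.sqrt(((frame[li] - frame[pi]) ** 2).sum()))
                    dists.append(d)
                    if d < cutoff:
                        hits += 1
                freqs.append(hits / traj.n_frames)
            if any(f > min_freq for f in freqs):
                dists = np.array(dists)
                permanent = bool(np.all(dists < cutoff)
                                 and dists.std(ddof=1) < 0.25)
                out[(li, pi)] = (tuple(freqs),
                                 "permanent" if permanent else "transient")
    return out


class TestCandidateContacts:
    def test_hand_counted_three_frames(self):
        traj = traj_with_distances([3.5, 3.9, 4.2])
        recs = candidate_contacts([traj], [0], [1])
        assert len(recs) == 1
        assert recs[0].frequencies == (pytest.approx(2 / 3),)

    def test_exactly_cutoff_distance_is_not_contact(self):
        traj = traj_with_distances([4.0, 4.0, 4.0])
        assert candidate_contacts([traj], [0], [1]) == []

    def test_frequency_exactly_half_is_dropped(self):
        traj = traj_with_distances([3.0, 3.0, 5.0, 5.0])  # freq exactly 0.5
        assert candidate_contacts([traj], [0], [1]) == []

    def test_planted_frequencies_select_expected_pairs(self):
        plan = [(0.2, 3.3, 0.2), (0.55, 3.3, 0.2), (1.0, 3.2, 0.15)]
        traj = synth_contact_trajectory(plan, 1000, seed=8)
        lig = traj.topology.group("ligand")
        prot = traj.topology.group("protein")
        recs = candidate_contacts([traj], lig, prot)
        kept = {r.pair_label for r in recs}
        assert kept == {(2, 3), (4, 5)}

    def test_retained_in_one_of_two_simulations_suffices(self):
        t_hi = traj_with_distances([3.0] * 10)
        t_lo = traj_with_distances([6.0] * 10)
        recs = candidate_contacts([t_hi, t_lo], [0], [1])
        assert len(recs) == 1
        assert recs[0].frequencies == (1.0, 0.0)

    def test_empty_atom_set_rejected(self):
        traj = traj_with_distances([3.0])
        with pytest.raises(ValueError, match="empty"):
            candidate_contacts([traj], [], [1])

    def test_hydrogens_excluded_from_census(self):
        atoms = [Atom(1, "H1", "H", 1.0, 200, "LIG"),
                 Atom(2, "CA", "C", 12.0, 5, "GLU")]
        topo = Topology(atoms=atoms)
        frames = np.zeros((3, 2, 3))
        frames[:, 1, 0] = 3.0
        traj = Trajectory(topology=topo, frames=frames, dt=1.0)
        with pytest.raises(ValueError, match="empty"):
            candidate_contacts([traj], [0], [1])


class TestClassify:
    def test_planted_low_sd_full_frequency_is_permanent(self):
        traj = synth_contact_trajectory([(1.0, 3.2, 0.15)], 1000, seed=9)
        recs = candidate_contacts(
            [traj], traj.topology.group("ligand"),
            traj.topology.group("protein"))
        assert recs[0].contact_class == "permanent"

    def test_high_sd_full_frequency_is_transient(self):
        rng = np.random.default_rng(10)
        d = np.clip(rng.normal(3.0, 0.4, 2000), 0.5, 3.999)
        traj = traj_with_distances(d)
        recs = candidate_contacts([traj], [0], [1])
        assert recs[0].pooled_sd > 0.25
        assert recs[0].contact_class == "transient"

    def test_single_missed_frame_is_transient(self):
        d = np.full(100, 3.2)
        d[57] = 4.5  # one frame out of contact despite low SD overall
        traj = traj_with_distances(d)
        recs = candidate_contacts([traj], [0], [1])
        assert recs[0].contact_class == "transient"

    def test_sd_exactly_at_threshold_is_transient(self):
        rec_at = candidate_contacts(
            [traj_with_distances([3.0, 3.0])], [0], [1])[0]
        rec_at.pooled_sd = 0.25
        assert classify(rec_at) == "transient"

    def test_standard_plan_labels_fully_recovered(self):
        plan = [
            ContactPlanEntry(1.0, 3.2, 0.10),   # permanent
            ContactPlanEntry(1.0, 3.0, 0.45),   # transient by SD
            ContactPlanEntry(0.6, 3.4, 0.2),    # transient by frequency
            ContactPlanEntry(0.2, 3.4, 0.2),    # not even candidate
        ]
        traj = synth_contact_trajectory(plan, 1500, seed=11)
        recs = candidate_contacts([traj], traj.topology.group("ligand"),
                                  traj.topology.group("protein"))
        by_pair = {r.ligand_index: r.contact_class for r in recs}
        assert by_pair == {0: "permanent", 2: "transient", 4: "transient"}

    def test_permanent_subset_of_candidates(self):
        plan = [(1.0, 3.2, 0.1), (0.7, 3.5, 0.3), (0.4, 3.5, 0.3)]
        traj = synth_contact_trajectory(plan, 800, seed=12)
        recs = candidate_contacts([traj], traj.topology.group("ligand"),
                                  traj.topology.group("protein"))
        perm = [r for r in recs if r.contact_class == "permanent"]
        assert set(r.pair_label for r in perm) <= set(
            r.pair_label for r in recs)


class TestOracleEquivalence:
    def test_census_matches_brute_force_exactly(self):
        plan = [(1.0, 3.2, 0.12), (0.8, 3.5, 0.25), (0.5, 3.4, 0.2),
                (0.1, 3.4, 0.2)]
        trajs = [synth_contact_trajectory(plan, 100, seed=s)
                 for s in range(3)]
        lig = trajs[0].topology.group("ligand")
        prot = trajs[0].topology.group("protein")
        recs = candidate_contacts(trajs, lig, prot)
        oracle = brute_force_census(trajs, lig, prot)
        assert {r.pair_label for r in recs} == set(oracle)
        for r in recs:
            freqs, label = oracle[r.pair_label]
            assert r.frequencies == tuple(pytest.approx(f) for f in freqs)
            assert r.contact_class == label


class TestContactMap:
    def _map_topology(self):
        atoms = [
            Atom(1, "C1", "C", 12.0, 200, "LIG"),  # Tol moiety
            Atom(2, "C2", "C", 12.0, 200, "LIG"),  # core moiety
            Atom(3, "CE", "C", 12.0, 87, "HIS"),
            Atom(4, "CB", "C", 12.0, 82, "TYR"),
        ]
        return Topology(atoms=atoms, groups={
            "ligand": (0, 1), "protein": (2, 3),
            "Tol": (0,), "core": (1,), "solvent": ()})

    def test_single_pair_single_cell(self):
        topo = self._map_topology()
        frames = np.array([[[0, 0, 0], [0, 50, 0],
                            [3.0, 0, 0], [50, 50, 0]]], dtype=float)
        traj = Trajectory(topology=topo, frames=frames, dt=1.0)
        cmap = contact_map([traj], {"Tol": topo.group("Tol"),
                                    "core": topo.group("core")},
                           topo.group("protein"))
        assert cmap.row_names == ["Tol", "core"]
        assert cmap.residue_labels == ["HIS87", "TYR82"]
        expected = np.zeros((2, 2))
        expected[0, 0] = 1.0  # Tol-His87
        np.testing.assert_array_equal(cmap.counts, expected)

    def test_cell_sum_equals_total_cross_contacts(self):
        rng = np.random.default_rng(13)
        topo = self._map_topology()
        frames = rng.uniform(0, 6, size=(50, 4, 3))
        traj = Trajectory(topology=topo, frames=frames, dt=1.0)
        cmap = contact_map([traj], {"Tol": (0,), "core": (1,)}, (2, 3))
        total = 0
        for frame in frames:
            for li in (0, 1):
                for pi in (2, 3):
                    if np.linalg.norm(frame[li] - frame[pi]) < 4.0:
                        total += 1
        assert cmap.counts.sum() == pytest.approx(total / 50)

    def test_permutation_invariance_under_frame_reorder(self):
        rng = np.random.default_rng(14)
        topo = self._map_topology()
        frames = rng.uniform(0, 6, size=(30, 4, 3))
        t1 = Trajectory(topology=topo, frames=frames, dt=1.0)
        t2 = Trajectory(topology=topo, frames=frames[::-1], dt=1.0)
        m1 = contact_map([t1], {"Tol": (0,)}, (2, 3))
        m2 = contact_map([t2], {"Tol": (0,)}, (2, 3))
        np.testing.assert_allclose(m1.counts, m2.counts)

    def test_ensemble_average_is_mean_of_per_sim_averages(self):
        topo = self._map_topology()
        near = np.array([[[0, 0, 0], [0, 50, 0], [3.0, 0, 0], [50, 50, 0]]])
        far = np.array([[[0, 0, 0], [0, 50, 0], [9.0, 0, 0], [50, 50, 0]]])
        t_near = Trajectory(topology=topo, frames=near, dt=1.0)
        t_far = Trajectory(topology=topo, frames=far, dt=1.0)
        cmap = contact_map([t_near, t_far], {"Tol": (0,)}, (2, 3))
        assert cmap.counts[0, 0] == pytest.approx(0.5)


class TestBridgingWaters:
    def _setup(self, water_x):
        topo = pair_topology(n_extra_waters=1)
        frames = np.zeros((1, 3, 3))
        frames[0, 1, 0] = 7.0       # ligand at 0, residue at 7
        frames[0, 2, 0] = water_x
        traj = Trajectory(topology=topo, frames=frames, dt=1.0)
        return topo, traj

    def test_water_bridging_both_counts_one(self):
        topo, traj = self._setup(3.5)  # within 4 of both (3.5 and 3.5)
        layer = bridging_waters([traj], {"core": (0,)}, (1,), (2,))
        assert layer[0, 0] == 1.0

    def test_water_near_moiety_only_counts_zero(self):
        topo, traj = self._setup(1.0)  # 1.0 from ligand, 6.0 from residue
        layer = bridging_waters([traj], {"core": (0,)}, (1,), (2,))
        assert layer[0, 0] == 0.0

    def test_no_solvent_warns_and_returns_zero(self):
        topo = pair_topology()
        traj = traj_with_distances([3.0], topo)
        with pytest.warns(UserWarning, match="no solvent"):
            layer = bridging_waters([traj], {"core": (0,)}, (1,), ())
        assert layer.sum() == 0.0

    def test_bin_boundaries_left_open_right_closed(self):
        assert water_bin_label(0.5) is None
        assert water_bin_label(1.0) == "]0.5;1]"
        assert water_bin_label(1.2) == "]1;1.5]"
        assert water_bin_label(2.0) == "]1.5;2]"


class TestHbondStats:
    def _traj(self, donor, hydrogen, acceptor):
        atoms = [Atom(1, "N", "N", 14.0, 56, "ILE"),
                 Atom(2, "H", "H", 1.0, 56, "ILE"),
                 Atom(3, "O1", "O", 16.0, 200, "LIG")]
        topo = Topology(atoms=atoms)
        frames = np.array([[donor, hydrogen, acceptor]], dtype=float)
        return Trajectory(topology=topo, frames=frames, dt=1.0)

    def test_collinear_geometry(self):
        traj = self._traj([0, 0, 0], [1.0, 0, 0], [2.9, 0, 0])
        hb = hbond_stats([traj], 0, 1, 2)
        assert hb.mean_angle == pytest.approx(180.0)
        assert hb.mean_distance == pytest.approx(1.9)

    def test_right_angle_geometry(self):
        traj = self._traj([0, 0, 0], [1.0, 0, 0], [1.0, 1.9, 0])
        hb = hbond_stats([traj], 0, 1, 2)
        assert hb.mean_angle == pytest.approx(90.0)

    def test_nascent_bond_not_formed_under_defaults(self):
        # geometry built to a mean H...A distance of 2.78 A and angle 123 deg:
        # a nascent interaction that fails the formed-bond criteria and counts
        # as a van der Waals contact instead
        rng = np.random.default_rng(15)
        frames = []
        for _ in range(200):
            d = rng.normal(2.78, 0.1)
            ang = np.radians(rng.normal(123.0, 2.0))
            h = np.array([1.0, 0, 0])
            dvec = -h  # donor at origin
            a = h + d * np.array([-np.cos(ang), np.sin(ang), 0.0])
            frames.append([[0, 0, 0], h, a])
        atoms = [Atom(1, "N", "N", 14.0, 56, "ILE"),
                 Atom(2, "H", "H", 1.0, 56, "ILE"),
                 Atom(3, "O1", "O", 16.0, 200, "LIG")]
        traj = Trajectory(topology=Topology(atoms=atoms),
                          frames=np.array(frames), dt=1.0)
        hb = hbond_stats([traj], 0, 1, 2)
        assert hb.mean_distance == pytest.approx(2.78, abs=0.05)
        assert hb.mean_angle == pytest.approx(123.0, abs=1.0)
        assert not hb.formed

    def test_distinct_atoms_required(self):
        traj = self._traj([0, 0, 0], [1, 0, 0], [2, 0, 0])
        with pytest.raises(ValueError, match="distinct"):
            hbond_stats([traj], 0, 0, 2)
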