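"""Detectors, persistence arithmetic, ligand network and lipid census."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (brute_force_hbonds, brute_force_salt_bridges,
                      random_mixed_frame)
from helixdyn.core import AtomRecord, Frame, ResidueKey, Trajectory
from helixdyn.interactions import (detect_hbonds, detect_salt_bridges,
                                   hbond_pair_detector, ligand_contact_network,
                                   lipid_hbond_counts, persistence)
from helixdyn.structure_io import annotate_chemistry
from helixdyn.synthetic_data import (AtomSpec, InteractionSchedule, NoiseModel,
                                     build_ideal_helix, build_membrane_mock,
                                     generate_trajectory)


def _pair_frame(distance: float, angle_deg: float) -> tuple[Frame, "object"]:
    """Minimal donor(H)/acceptor system at a controlled geometry.

    A lysine-like donor (NZ with one HZ1 along +x) and a backbone carbonyl O
    acceptor placed at the given donor-acceptor distance and off-axis angle.
    """
    ang = np.radians(angle_deg)
    acceptor_pos = np.array([distance * np.cos(ang), distance * np.sin(ang), 0.0])
    atoms = [
        AtomRecord(1, "NZ", "N", "LYS", 1, "A"),
        AtomRecord(2, "HZ1", "H", "LYS", 1, "A"),
        AtomRecord(3, "O", "O", "GLY", 2, "A"),
        AtomRecord(4, "N", "N", "GLY", 2, "A"),
        AtomRecord(5, "H", "H", "GLY", 2, "A"),
    ]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        acceptor_pos,
        acceptor_pos + [20.0, 0.0, 0.0],
        acceptor_pos + [21.0, 0.0, 0.0],
    ])
    frame = Frame(atoms, coords)
    return frame, annotate_chemistry(frame)


class TestHBondCriteria:
    @pytest.mark.parametrize("distance,angle,expected", [
        (2.9, 10.0, True),    # planted well inside both criteria
        (3.5, 0.0, True),     # inclusive distance boundary
        (3.2, 40.0, False),   # angle violation
        (3.2, 30.0, True),    # inclusive angle boundary
        (3.6, 0.0, False),    # distance violation
    ])
    def test_geometric_criteria(self, distance, angle, expected):
        frame, ann = _pair_frame(distance, angle)
        events = detect_hbonds(frame, None, None, ann)
        found = any(frame.atoms[e.donor].name == "NZ" for e in events)
        assert found == expected

    def test_symmetric_in_selections(self, helix_mixed):
        ann = annotate_chemistry(helix_mixed)
        sel_a = helix_mixed.select(resid_range=(1, 7))
        sel_b = helix_mixed.select(resid_range=(8, 15))
        ab = {(e.donor, e.acceptor)
              for e in detect_hbonds(helix_mixed, sel_a, sel_b, ann)}
        ba = {(e.donor, e.acceptor)
              for e in detect_hbonds(helix_mixed, sel_b, sel_a, ann)}
        assert ab == ba

    def test_rotation_translation_invariance(self, helix_mixed):
        ann = annotate_chemistry(helix_mixed)
        ref = {(e.donor, e.acceptor)
               for e in detect_hbonds(helix_mixed, None, None, ann)}
        theta = 1.1
        R = np.array([[1, 0, 0],
                      [0, np.cos(theta), -np.sin(theta)],
                      [0, np.sin(theta), np.cos(theta)]])
        moved = helix_mixed.transformed(R, np.array([-3.0, 8.0, 77.0]))
        got = {(e.donor, e.acceptor) for e in detect_hbonds(moved, None, None, ann)}
        assert got == ref

    def test_explicit_mode_on_h_free_frame_directs_to_heavy_only(self, helix15):
        heavy_idx = [i for i, a in enumerate(helix15.atoms) if a.element != "H"]
        heavy = Frame([helix15.atoms[i] for i in heavy_idx],
                      helix15.coords[heavy_idx])
        ann = annotate_chemistry(heavy)  # explicit_h on an H-free structure
        with pytest.raises(ValueError, match="heavy_only"):
            detect_hbonds(heavy, None, None, ann)

    def test_heavy_only_mode_applies_distance_criterion_alone(self):
        frame, _ = _pair_frame(3.3, 60.0)  # would fail the angle criterion
        heavy_idx = [i for i, a in enumerate(frame.atoms) if a.element != "H"]
        heavy = Frame([frame.atoms[i] for i in heavy_idx], frame.coords[heavy_idx])
        ann = annotate_chemistry(heavy, mode="heavy_only")
        events = detect_hbonds(heavy, None, None, ann)
        assert any(heavy.atoms[e.donor].name == "NZ" and e.angle is None
                   for e in events)


class TestSaltBridgeCriteria:
    def _ek_frame(self, nz_to_oe1: float) -> Frame:
        atoms = [
            AtomRecord(1, "NZ", "N", "LYS", 1, "A"),
            AtomRecord(2, "OE1", "O", "GLU", 5, "A"),
            AtomRecord(3, "OE2", "O", "GLU", 5, "A"),
        ]
        coords = np.array([[0.0, 0.0, 0.0],
                           [nz_to_oe1, 0.0, 0.0],
                           [nz_to_oe1 + 2.2, 0.0, 0.0]])
        return Frame(atoms, coords)

    @pytest.mark.parametrize("distance,expected", [
        (6.4, True), (6.5, True), (6.6, False),
    ])
    def test_minimum_heavy_atom_distance_boundary(self, distance, expected):
        frame = self._ek_frame(distance)
        ann = annotate_chemistry(frame)
        events = detect_salt_bridges(frame, ann)
        assert bool(events) == expected
        if events:
            assert events[0].min_distance == pytest.approx(distance)
            # centroid (group) distance reported alongside the minimum
            assert events[0].group_distance == pytest.approx(distance + 1.1)

    def test_same_sign_groups_never_bridge(self):
        atoms = [AtomRecord(1, "NZ", "N", "LYS", 1, "A"),
                 AtomRecord(2, "NZ", "N", "LYS", 5, "A")]
        frame = Frame(atoms, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        ann = annotate_chemistry(frame)
        assert detect_salt_bridges(frame, ann) == []

    def test_his_bridges_only_when_protonated(self):
        atoms = [AtomRecord(1, "OD1", "O", "ASP", 1, "A"),
                 AtomRecord(2, "OD2", "O", "ASP", 1, "A"),
                 AtomRecord(3, "NE2", "N", "HIS", 9, "A"),
                 AtomRecord(4, "ND1", "N", "HIS", 9, "A")]
        coords = np.array([[0.0, 0, 0], [2.2, 0, 0], [4.0, 0, 0], [5.2, 0, 0]])
        frame = Frame(atoms, coords)
        assert detect_salt_bridges(frame, annotate_chemistry(frame)) == []
        charged = annotate_chemistry(frame, his_protonated=True)
        events = detect_salt_bridges(frame, charged)
        assert len(events) == 1 and events[0].positive == ResidueKey("A", 9)


class TestBruteForceOracle:
    def test_detectors_match_all_pairs_reference(self):
        rng = np.random.default_rng(1234)
        for trial in range(20):
            frame = random_mixed_frame(rng)
            assert frame.n_atoms <= 500
            ann = annotate_chemistry(frame)
            fast = {(e.donor, e.acceptor)
                    for e in detect_hbonds(frame, None, None, ann)}
            assert fast == brute_force_hbonds(frame, ann)
            fast_sb = {(e.negative, e.positive)
                       for e in detect_salt_bridges(frame, ann)}
            assert fast_sb == brute_force_salt_bridges(frame, ann)


class TestPersistence:
    def test_planted_arithmetic(self, helix_mixed):
        presence = np.array([True] * 19 + [False] * 31)
        sched = InteractionSchedule(AtomSpec("A", 2, "NZ"),
                                    AtomSpec("A", 13, "OE1"),
                                    presence=presence)
        traj = generate_trajectory(helix_mixed, NoiseModel(0.2), [sched],
                                   n_frames=50, seed=8)
        ann = annotate_chemistry(traj.frame(0))
        det = hbond_pair_detector(traj, ResidueKey("A", 2),
                                  ResidueKey("A", 13), ann)
        rec = persistence(traj, "K2-E13", det)
        assert rec.percent == 38.0
        always = InteractionSchedule(AtomSpec("A", 2, "NZ"),
                                     AtomSpec("A", 13, "OE1"),
                                     presence=[True] * 50)
        traj2 = generate_trajectory(helix_mixed, NoiseModel(0.2), [always],
                                    n_frames=50, seed=8)
        assert persistence(traj2, "K2-E13",
                           hbond_pair_detector(traj2, ResidueKey("A", 2),
                                               ResidueKey("A", 13), ann)
                           ).percent == 100.0

    def test_missing_pair_raises_with_names(self, helix_mixed):
        traj = generate_trajectory(helix_mixed, NoiseModel(0.1),
                                   n_frames=3, seed=0)
        ann = annotate_chemistry(traj.frame(0))
        with pytest.raises(ValueError, match="A:99"):
            hbond_pair_detector(traj, ResidueKey("A", 2), ResidueKey("A", 99), ann)

    def test_discard_prefix_excluded_from_denominator(self, helix_mixed):
        presence = [False] * 10 + [True] * 20 + [False] * 20
        sched = InteractionSchedule(AtomSpec("A", 2, "NZ"),
                                    AtomSpec("A", 13, "OE1"), presence=presence)
        traj = generate_trajectory(helix_mixed, NoiseModel(0.2), [sched],
                                   n_frames=50, seed=2, discard_prefix=10)
        ann = annotate_chemistry(traj.frame(0))
        det = hbond_pair_detector(traj, ResidueKey("A", 2),
                                  ResidueKey("A", 13), ann)
        rec = persistence(traj, "K2-E13", det)
        assert rec.frames_analyzed == 40
        assert rec.percent == 50.0

    def test_concatenation_is_frame_weighted_mean(self, helix_mixed):
        p1 = [True] * 6 + [False] * 14      # 30% of 20
        p2 = [True] * 27 + [False] * 3      # 90% of 30
        ann = annotate_chemistry(helix_mixed)
        key_a, key_b = ResidueKey("A", 2), ResidueKey("A", 13)

        def run(presence, seed):
            sched = InteractionSchedule(AtomSpec("A", 2, "NZ"),
                                        AtomSpec("A", 13, "OE1"),
                                        presence=presence)
            return generate_trajectory(helix_mixed, NoiseModel(0.2), [sched],
                                       n_frames=len(presence), seed=seed)

        t1, t2 = run(p1, 3), run(p2, 4)
        cat = t1.concatenated(t2)
        det = hbond_pair_detector(cat, key_a, key_b, ann)
        whole = persistence(cat, "pair", det).percent
        part1 = persistence(t1, "pair",
                            hbond_pair_detector(t1, key_a, key_b, ann)).percent
        part2 = persistence(t2, "pair",
                            hbond_pair_detector(t2, key_a, key_b, ann)).percent
        weighted = (20 * part1 + 30 * part2) / 50
        assert whole == pytest.approx(weighted)

    @given(n_on=st.integers(0, 40), n_total=st.just(40))
    @settings(max_examples=20, deadline=None)
    def test_persistence_bounded_0_100(self, n_on, n_total):
        present = np.zeros(n_total, bool)
        present[:n_on] = True
        calls = iter(present)  # stub detector replays the planted truth
        helix = build_ideal_helix("AAAA")
        traj = Trajectory(helix.atoms,
                          np.repeat(helix.coords[None], n_total, axis=0))
        rec = persistence(traj, "stub", lambda fr: next(calls))
        assert 0.0 <= rec.percent <= 100.0
        assert rec.percent == pytest.approx(100.0 * n_on / n_total)


class TestLigandNetwork:
    def _static_pair_traj(self, distance: float) -> Trajectory:
        atoms = [AtomRecord(1, "NZ", "N", "LYS", 1, "A"),
                 AtomRecord(2, "O1B", "O", "GDP", 901, "X")]
        coords = np.array([[0.0, 0, 0], [distance, 0, 0]])
        return Trajectory(atoms, np.repeat(coords[None], 4, axis=0))

    @pytest.mark.parametrize("distance,cls", [
        (3.4, "tight"), (3.8, "loose"), (4.2, "none"),
    ])
    def test_distance_classes(self, distance, cls):
        traj = self._static_pair_traj(distance)
        series = ligand_contact_network(
            traj, [(("A", 1, "NZ"), ("X", 901, "O1B"))])
        assert set(series[0].classes) == {cls}

    def test_unresolvable_pair_raises(self):
        traj = self._static_pair_traj(3.0)
        with pytest.raises(KeyError):
            ligand_contact_network(traj, [(("A", 1, "NZ"), ("X", 901, "O9X"))])


class TestLipidCensus:
    def test_planted_pe_bond_counts_pe_one_pc_zero(self):
        helix = build_ideal_helix("AKES", chain="P")
        mem = build_membrane_mock(1, 1, seed=0)
        atoms = list(helix.atoms) + [
            AtomRecord(a.serial + helix.n_atoms, a.name, a.element, a.resname,
                       a.resid, a.chain) for a in mem.atoms]
        coords = np.concatenate([helix.coords, mem.coords + [40.0, 0, 0]])
        base = Frame(atoms, coords)
        # plant: PE amine 2.9 Å from a protein backbone O
        sched = InteractionSchedule(AtomSpec("L", 2, "N"),
                                    AtomSpec("P", 2, "O"), presence=[True] * 5)
        traj = generate_trajectory(base, NoiseModel(0.0), [sched],
                                   n_frames=5, seed=0)
        ann = annotate_chemistry(traj.frame(0))
        table = lipid_hbond_counts(traj, ann)
        assert table["PE"]["mean_per_frame"] == pytest.approx(1.0)
        assert table["PC"]["mean_per_frame"] == 0.0

    def test_pe_majority_ordering(self):
        helix = build_ideal_helix("AKESAKES", chain="P")
        mem = build_membrane_mock(2, 3, seed=0)
        atoms = list(helix.atoms) + [
            AtomRecord(a.serial + helix.n_atoms, a.name, a.element, a.resname,
                       a.resid, a.chain) for a in mem.atoms]
        base = Frame(atoms, np.concatenate([helix.coords,
                                            mem.coords + [40.0, 0, 0]]))
        schedules = [
            InteractionSchedule(AtomSpec("L", k, "N"), AtomSpec("P", r, "O"),
                                presence=[True] * 4)
            for k, r in ((2, 2), (4, 3), (5, 4))          # 3 PE donations
        ] + [
            InteractionSchedule(AtomSpec("P", 6, "N"), AtomSpec("L", 1, "O13"),
                                presence=[True] * 4)      # 1 PC acceptor bond
        ]
        traj = generate_trajectory(base, NoiseModel(0.0), schedules,
                                   n_frames=4, seed=0)
        ann = annotate_chemistry(traj.frame(0))
        table = lipid_hbond_counts(traj, ann)
        assert table["PE"]["mean_per_frame"] > table["PC"]["mean_per_frame"]

    def test_absent_species_reports_zero(self):
        mem = build_membrane_mock(2, 0, seed=0)
        helix = build_ideal_helix("AKES", chain="P")
        atoms = list(helix.atoms) + [
            AtomRecord(a.serial + helix.n_atoms, a.name, a.element, a.resname,
                       a.resid, a.chain) for a in mem.atoms]
        base = Frame(atoms, np.concatenate([helix.coords,
                                            mem.coords + [40.0, 0, 0]]))
        traj = generate_trajectory(base, NoiseModel(0.0), n_frames=3, seed=0)
        table = lipid_hbond_counts(traj, annotate_chemistry(base))
        assert "PE" not in table
        assert table["PC"]["total"] == 0.0
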