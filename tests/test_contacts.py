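import numpy as np
import pandas as pd
import pytest

from nucleodope.contacts import (
    HBondContact,
    StackContact,
    aggregate_contacts,
    classify_base_frame,
    detect_hbonds,
    detect_pi_stacking,
    distinct_stacked_bases,
    hbond_lifetime,
    hbond_presence_matrix,
    occurrence_probabilities,
    stacked_base_count,
)
from nucleodope.definitions import compile_interaction_sites
from nucleodope.model import AnalysisConfig, Frame, InteractionLabel
from nucleodope.synthetic import ScenarioSpec, synth_interaction_trajectory

from oracles import hbonds_bruteforce, stack_pairs_bruteforce


def _stack(base_rid, mol, vsep=0.35, frame=0):
    return StackContact(
        frame_index=frame,
        base_residue_id=base_rid,
        base_ring_id=0,
        alq_molecule_id=mol,
        quinoline_ring_id=1,
        vertical_separation=vsep,
        lateral_offset=0.0,
        interplanar_angle=0.0,
    )


def _hbond(base_rid, base_mol, alq_mol, frame=0):
    return HBondContact(
        frame_index=frame,
        donor_molecule_id=base_mol,
        donor_residue_id=base_rid,
        donor_atom=0,
        hydrogen_atom=1,
        acceptor_molecule_id=alq_mol,
        acceptor_residue_id=999,
        acceptor_atom=2,
        distance=0.29,
        angle=10.0,
    )


class TestClassification:
    def test_stack_and_hbond_with_same_molecule_is_multisite_type_i(self):
        # the thymine mode: one Alq3 provides both interactions
        label, partners = classify_base_frame(
            [_stack(7, mol=5)], [_hbond(7, base_mol=100, alq_mol=5)], 7, 100
        )
        assert label is InteractionLabel.TYPE_I
        assert partners["stack_partner"] == partners["hbond_partner"] == 5

    def test_hbond_and_stack_with_different_molecules_is_type_ii(self):
        # the adenine mode: H-bond to one Alq3, stack on a neighbour
        label, partners = classify_base_frame(
            [_stack(7, mol=9)], [_hbond(7, base_mol=100, alq_mol=5)], 7, 100
        )
        assert label is InteractionLabel.TYPE_II
        assert partners == {"stack_partner": 9, "hbond_partner": 5}

    def test_no_contacts_is_none(self):
        label, _ = classify_base_frame([], [], 7, 100)
        assert label is InteractionLabel.NONE

    def test_type_i_tie_broken_by_smallest_vertical_separation(self):
        stacks = [_stack(7, mol=5, vsep=0.40), _stack(7, mol=6, vsep=0.30)]
        hbonds = [_hbond(7, 100, 5), _hbond(7, 100, 6)]
        label, partners = classify_base_frame(stacks, hbonds, 7, 100)
        assert label is InteractionLabel.TYPE_I
        assert partners["stack_partner"] == 6

    def test_priority_single_interaction_labels(self):
        label, _ = classify_base_frame([], [_hbond(7, 100, 5)], 7, 100)
        assert label is InteractionLabel.HBOND_ONLY
        label, _ = classify_base_frame([_stack(7, 5)], [], 7, 100)
        assert label is InteractionLabel.PI_ONLY


@pytest.fixture(scope="module")
def one_base():
    spec = ScenarioSpec(
        n_alq3=2, sequence="T", fractions={"TypeI": 1.0}, n_frames=10, seed=1
    )
    traj, truth = synth_interaction_trajectory(spec)
    rings, das = compile_interaction_sites(traj.topology)
    return traj, truth, rings, das


class TestDetectionOnConstructedGeometry:
    def test_constructed_type_i_geometry_detected_every_frame(self, one_base):
        traj, truth, rings, das = one_base
        config = AnalysisConfig()
        for frame in traj.frames:
            stacks = detect_pi_stacking(frame, rings, config)
            assert len(stacks) == 1
            assert stacks[0].vertical_separation == pytest.approx(0.35, abs=1e-9)
            hbonds = detect_hbonds(frame, das, config)
            assert len(hbonds) == 1
            assert hbonds[0].distance == pytest.approx(0.29, abs=1e-9)
            assert hbonds[0].angle == pytest.approx(10.0, abs=1e-6)

    def test_vertical_separation_beyond_cutoff_is_not_stacked(self, one_base):
        traj, _, rings, _ = one_base
        config = AnalysisConfig(stacking_cutoff=0.30)  # 0.35 now exceeds it
        assert detect_pi_stacking(traj.frames[0], rings, config) == []

    def test_hbond_distance_beyond_cutoff_rejected(self, one_base):
        traj, _, _, das = one_base
        config = AnalysisConfig(hbond_distance_cutoff=0.28)  # 0.29 now exceeds it
        assert detect_hbonds(traj.frames[0], das, config) == []

    def test_stack_count_monotone_in_cutoff(self, one_base):
        traj, _, rings, _ = one_base
        counts = []
        for cutoff in (0.2, 0.36, 0.45, 0.6, 0.9):
            config = AnalysisConfig(stacking_cutoff=cutoff)
            n = sum(
                len(detect_pi_stacking(f, rings, config)) for f in traj.frames
            )
            counts.append(n)
        assert counts == sorted(counts)


class TestOracleEquivalence:
    def test_stacking_matches_bruteforce_on_random_frames(self):
        from conftest import random_ring_fixture

        config = AnalysisConfig()
        for seed in range(20):
            positions, top, rings, das = random_ring_fixture(seed)
            frame = Frame(time=0.0, positions=positions, topology=top)
            got = detect_pi_stacking(frame, rings, config)
            base_rings = [r for r in rings if r.kind == "base"]
            quin_rings = [r for r in rings if r.kind == "quinoline"]
            got_pairs = {
                (
                    next(i for i, b in enumerate(base_rings) if b.ring_id == c.base_ring_id),
                    next(i for i, q in enumerate(quin_rings) if q.ring_id == c.quinoline_ring_id),
                )
                for c in got
            }
            expected = stack_pairs_bruteforce(
                positions, base_rings, quin_rings,
                config.stacking_cutoff, config.lateral_guard,
            )
            assert got_pairs == expected

    def test_hbonds_match_bruteforce_on_random_frames(self):
        from conftest import random_ring_fixture

        # widened criteria so random geometry produces hits to compare
        config = AnalysisConfig(hbond_distance_cutoff=0.9, hbond_angle_cutoff=70.0)
        total = 0
        for seed in range(20):
            positions, top, rings, das = random_ring_fixture(seed + 100)
            frame = Frame(time=0.0, positions=positions, topology=top)
            got = {
                (
                    int(np.nonzero((das.donors[:, 0] == c.donor_atom))[0][0]),
                    int(np.nonzero(das.acceptors == c.acceptor_atom)[0][0]),
                )
                for c in detect_hbonds(frame, das, config)
            }
            expected = hbonds_bruteforce(
                positions, das, config.hbond_distance_cutoff, config.hbond_angle_cutoff
            )
            assert got == expected
            total += len(expected)
        assert total > 0  # the fixture must actually exercise the criteria


class TestAggregation:
    def test_closed_loop_labels_on_noise_free_scenario(self, tiny_scenario):
        spec, traj, truth, rings, das = tiny_scenario
        table = aggregate_contacts(traj, rings, das, AnalysisConfig())
        merged = truth.merge(
            table.labels, on=["frame", "base_index"], suffixes=("_true", "_got")
        )
        assert (merged["label_true"] == merged["label_got"]).all()

    def test_probability_partition_sums_to_100(self, tiny_scenario):
        _, traj, _, rings, das = tiny_scenario
        table = aggregate_contacts(traj, rings, das, AnalysisConfig())
        assert sum(table.probabilities.values()) == pytest.approx(100.0)
        assert all(v >= 0 for v in table.counts.values())

    def test_probabilities_invariant_to_frame_order(self, tiny_scenario):
        _, traj, _, rings, das = tiny_scenario
        from nucleodope.model import Trajectory

        table = aggregate_contacts(traj, rings, das, apply_window=False)
        rev_frames = [
            Frame(time=i * traj.dt, positions=f.positions, topology=f.topology)
            for i, f in enumerate(reversed(traj.frames))
        ]
        rev = Trajectory(frames=rev_frames, dt=traj.dt)
        table_rev = aggregate_contacts(rev, rings, das, apply_window=False)
        assert table.probabilities == pytest.approx(table_rev.probabilities)

    def test_all_zero_counts_flagged_as_undefined(self):
        assert occurrence_probabilities({"TypeI": 0}) == {}

    def test_negative_counts_rejected(self):
        from nucleodope.errors import DataError

        with pytest.raises(DataError):
            occurrence_probabilities({"TypeI": -1})


class TestStackedBaseCount:
    def test_alternating_five_and_nine_stacked_bases(self):
        frame_a = [_stack(rid, mol=rid, frame=0) for rid in range(5)]
        frame_b = [_stack(rid, mol=rid, frame=1) for rid in range(9)]
        counts = distinct_stacked_bases([frame_a, frame_b] * 10)
        assert counts.mean() == pytest.approx(7.0)
        assert counts.std() == pytest.approx(2.0)  # two-point population sd

    def test_constant_stacked_count_has_zero_sd(self):
        spec = ScenarioSpec(
            n_alq3=14, sequence="TTTTTTT", fractions={"PiOnly": 1.0},
            n_frames=6, seed=3,
        )
        traj, _ = synth_interaction_trajectory(spec)
        rings, _ = compile_interaction_sites(traj.topology)
        mean, sd = stacked_base_count(traj, rings)
        assert (mean, sd) == (7.0, 0.0)

    def test_all_none_scenario_counts_zero(self):
        spec = ScenarioSpec(
            n_alq3=4, sequence="TT", fractions={}, n_frames=5, seed=3
        )
        traj, _ = synth_interaction_trajectory(spec)
        rings, das = compile_interaction_sites(traj.topology)
        mean, sd = stacked_base_count(traj, rings)
        assert (mean, sd) == (0.0, 0.0)
        config = AnalysisConfig()
        assert all(
            detect_hbonds(f, das, config) == [] for f in traj.frames
        )


class TestLifetimes:
    def test_bond_present_every_frame(self):
        presence = np.ones((1, 100), dtype=bool)
        summary = hbond_lifetime(presence, dt=2.0)
        assert summary.mean_lifetime == pytest.approx(200.0)

    def test_alternating_presence_gives_dt(self):
        presence = np.array([[True, False] * 50])
        summary = hbond_lifetime(presence, dt=2.0)
        assert summary.mean_lifetime == pytest.approx(2.0)

    def test_two_runs_average(self):
        row = [True] * 3 + [False] * 2 + [True] * 5 + [False]
        summary = hbond_lifetime(np.array([row]), dt=2.0)
        assert summary.mean_lifetime == pytest.approx(8.0)  # (6 + 10) / 2
        assert summary.n_events == 2

    def test_never_present_reports_zero_with_flag(self):
        summary = hbond_lifetime(np.zeros((3, 10), dtype=bool), dt=2.0)
        assert summary.mean_lifetime == 0.0
        assert not summary.any_bond_observed

    def test_lifetime_at_least_dt_when_observed(self, tiny_scenario):
        _, traj, _, _, das = tiny_scenario
        config = AnalysisConfig()
        per_frame = [
            detect_hbonds(f, das, config, frame_index=i)
            for i, f in enumerate(traj.frames)
        ]
        presence, keys = hbond_presence_matrix(per_frame)
        summary = hbond_lifetime(presence, traj.dt, keys=keys, intermittent=True)
        assert summary.any_bond_observed
        assert summary.mean_lifetime >= traj.dt
        assert summary.intermittent_tau is not None and summary.intermittent_tau > 0
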