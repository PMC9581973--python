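import numpy as np
import pytest

from nucleodope.errors import ConfigError, DataError, ParseError
from nucleodope.io import (
    read_structure,
    read_trajectory,
    read_xy_table,
    write_structure,
    write_trajectory_xyz,
    write_xy_table,
)
from nucleodope.model import AnalysisConfig, Frame, Topology, Trajectory
from nucleodope.synthetic import ScenarioSpec, synth_interaction_trajectory


def small_frame():
    top = Topology(
        names=["N1", "C2", "O1"],
        elements=["N", "C", "O"],
        residue_names=["RES", "RES", "RES"],
        residue_ids=[1, 1, 1],
        molecule_ids=[0, 0, 0],
    )
    pos = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.0, 0.1, 0.0]])
    return Frame(time=0.0, positions=pos, topology=top)


class TestStructureIO:
    def test_hand_written_gro_positions_in_nm(self, tmp_path):
        gro = tmp_path / "three.gro"
        gro.write_text(
            "three atoms\n"
            "    3\n"
            "    1RES     N1    1   0.000   0.000   0.000\n"
            "    1RES     C2    2   0.100   0.000   0.000\n"
            "    1RES     O1    3   0.000   0.100   0.000\n"
            "   2.00000   2.00000   2.00000\n"
        )
        frame = read_structure(gro)
        assert frame.n_atoms == 3
        assert np.allclose(
            frame.positions, [[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0]], atol=1e-6
        )
        assert np.allclose(frame.box, [2.0, 2.0, 2.0])

    def test_pdb_angstrom_converted_to_nm(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  N1  RES A   1       1.234   0.000   5.000  1.00  0.00"
            "           N\n"
            "END\n"
        )
        frame = read_structure(pdb)
        assert frame.positions[0] == pytest.approx([0.1234, 0.0, 0.5], abs=1e-6)

    @pytest.mark.parametrize("ext", ["gro", "pdb"])
    def test_round_trip_to_format_precision(self, tmp_path, ext):
        frame = small_frame()
        path = tmp_path / f"out.{ext}"
        write_structure(frame, path)
        back = read_structure(path)
        assert back.n_atoms == frame.n_atoms
        assert list(back.topology.names) == list(frame.topology.names)
        assert np.allclose(back.positions, frame.positions, atol=1.5e-3)

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.gro"
        p.write_text("")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.xtc"
        p.write_text("junk")
        with pytest.raises(ParseError, match="unsupported"):
            read_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError, match="not found"):
            read_structure(tmp_path / "nope.gro")


class TestTrajectoryIO:
    def test_xyz_round_trip_preserves_frames_and_positions(self, tmp_path):
        spec = ScenarioSpec(n_alq3=2, sequence="T", n_frames=5, seed=2)
        traj, _ = synth_interaction_trajectory(spec)
        path = tmp_path / "traj.xyz"
        write_trajectory_xyz(traj, path)
        back = read_trajectory(path, topology=traj.topology, dt=traj.dt)
        assert back.n_frames == 5
        for f0, f1 in zip(traj.frames, back.frames):
            assert np.allclose(f0.positions, f1.positions, atol=1e-5)

    def test_five_frame_two_atom_xyz(self, tmp_path):
        body = "".join(
            f"2\nframe {i}\nC 0.0 0.0 {i}.0\nN 1.0 0.0 0.0\n" for i in range(5)
        )
        path = tmp_path / "t.xyz"
        path.write_text(body)
        traj = read_trajectory(path, dt=2.0)
        assert traj.n_frames == 5
        assert traj.times[-1] == pytest.approx(8.0)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\na\nC 0 0 0\nN 1 0 0\n3\nb\nC 0 0 0\nN 1 0 0\nO 2 0 0\n")
        with pytest.raises((ParseError, DataError)):
            read_trajectory(path, dt=1.0)

    def test_empty_trajectory_rejected(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("")
        with pytest.raises(ParseError):
            read_trajectory(path)


class TestWindowSelection:
    @pytest.fixture()
    def coarse_trajectory(self):
        top = Topology(
            names=["C1"], elements=["C"], residue_names=["RES"],
            residue_ids=[0], molecule_ids=[0],
        )
        frames = [
            Frame(time=i * 200.0, positions=np.zeros((1, 3)), topology=top)
            for i in range(100)
        ]
        return Trajectory(frames=frames, dt=200.0)

    def test_closed_10ns_window_keeps_51_frames(self, coarse_trajectory):
        window = coarse_trajectory.select_window(0.0, 10_000.0)
        assert window.n_frames == 51

    def test_window_selection_idempotent_and_ordered(self, coarse_trajectory):
        w1 = coarse_trajectory.select_window(2000.0, 12_000.0)
        w2 = w1.select_window(2000.0, 12_000.0)
        assert w1.n_frames == w2.n_frames
        assert np.all(np.diff(w2.times) > 0)
        assert np.array_equal(w1.times, w2.times)

    def test_final_window_via_config(self, coarse_trajectory):
        window = AnalysisConfig(window_duration=10_000.0).window(coarse_trajectory)
        assert window.n_frames == 51
        assert window.times[-1] == pytest.approx(19_800.0)

    def test_empty_window_rejected(self, coarse_trajectory):
        with pytest.raises(DataError):
            coarse_trajectory.select_window(50.0, 150.0)

    def test_inverted_window_rejected(self, coarse_trajectory):
        with pytest.raises(ConfigError):
            coarse_trajectory.select_window(100.0, 50.0)


class TestXYTables:
    def test_basic_two_columns(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("# header\n400 1.0\n401 2.0\n")
        x, y = read_xy_table(p)
        assert x.tolist() == [400.0, 401.0]
        assert y.tolist() == [1.0, 2.0]

    def test_shuffled_rows_sorted_ascending(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("405 5\n401 1\n403 3\n")
        x, _ = read_xy_table(p)
        assert x.tolist() == [401.0, 403.0, 405.0]

    def test_duplicate_x_collapsed_by_mean(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("400 1.0\n400 3.0\n500 1.0\n")
        x, y = read_xy_table(p)
        assert x.tolist() == [400.0, 500.0]
        assert y[0] == pytest.approx(2.0)

    def test_single_point_rejected(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("400 1.0\n")
        with pytest.raises(DataError):
            read_xy_table(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("400 1.0\noops\n")
        with pytest.raises(ParseError, match=":2:"):
            read_xy_table(p)

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "t.txt"
        write_xy_table([1.0, 2.0], [0.5, 0.25], p, header="x y")
        x, y = read_xy_table(p)
        assert np.allclose(x, [1, 2]) and np.allclose(y, [0.5, 0.25])


class TestModelValidation:
    def test_negative_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(stacking_cutoff=-0.1)

    def test_bad_window_order_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(window_start=5.0, window_end=1.0)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            AnalysisConfig.from_mapping({"stacking_cutof": 0.4})

    def test_duplicate_molecule_atom_pairs_rejected(self):
        with pytest.raises(DataError):
            Topology(
                names=["A", "B"], elements=["C", "C"], residue_names=["R", "R"],
                residue_ids=[0, 0], molecule_ids=[0, 0], atom_ids=[1, 1],
            )

    def test_non_finite_positions_rejected(self):
        top = Topology(
            names=["A"], elements=["C"], residue_names=["R"],
            residue_ids=[0], molecule_ids=[0],
        )
        with pytest.raises(DataError):
            Frame(time=0.0, positions=np.array([[np.nan, 0, 0]]), topology=top)
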