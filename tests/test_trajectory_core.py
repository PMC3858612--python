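import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mk_traj
from pairspace.trajectory_core import (
    Trajectory,
    align_dyad,
    path_length,
    pool_nights,
    read_trajectories_csv,
    subsample,
)

MIN = 60.0


class TestSubsample:
    @pytest.mark.parametrize(
        "minutes, interval, kept",
        [
            ([0, 1, 2, 5, 6, 10], 300, [0, 5, 10]),   # greedy forward scan
            ([], 300, []),                            # empty passes through
            ([0, 5, 10], 300, [0, 5, 10]),            # already on the grid
        ],
    )
    def test_greedy_rule(self, minutes, interval, kept):
        tr = mk_traj([m * MIN for m in minutes], range(len(minutes)), range(len(minutes)))
        out = subsample(tr, interval)
        assert out.t.tolist() == [k * MIN for k in kept]

    def test_first_fix_always_retained(self):
        tr = mk_traj([7, 8, 9], [0, 1, 2], [0, 0, 0])
        assert subsample(tr, 1000).t.tolist() == [7]

    @given(st.lists(st.integers(0, 5000), min_size=1, max_size=40, unique=True),
           st.integers(1, 600))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_and_spacing(self, seconds, interval):
        seconds = sorted(seconds)
        tr = mk_traj(seconds, np.zeros(len(seconds)), np.zeros(len(seconds)))
        once = subsample(tr, interval)
        assert np.all(np.diff(once.t) >= interval)
        twice = subsample(once, interval)
        assert once.t.tolist() == twice.t.tolist()


class TestAlignDyad:
    def test_identical_timestamps_all_paired(self):
        a = mk_traj([0, 60, 120], [0, 1, 2], [0, 0, 0], ind="m")
        b = mk_traj([0, 60, 120], [5, 6, 7], [0, 0, 0], ind="f")
        dy = align_dyad(a, b, tol=30)
        assert len(dy) == 3
        assert dy.male_id == "m" and dy.female_id == "f"

    def test_out_of_tolerance_fix_dropped(self):
        a = mk_traj([0, 600], [0, 0], [0, 0])
        b = mk_traj([5, 300], [1, 1], [0, 0], ind="b")
        dy = align_dyad(a, b, tol=60)
        assert len(dy) == 1 and dy.t[0] == 0.0

    def test_nearest_fix_chosen(self):
        a = mk_traj([0], [0], [0])
        b = mk_traj([0, 30], [10, 99], [0, 0], ind="b")
        dy = align_dyad(a, b, tol=60)
        assert dy.female_xy[0, 0] == 10  # b@0, the nearer fix

    def test_disjoint_windows_empty(self):
        a = mk_traj([0, 60], [0, 0], [0, 0])
        b = mk_traj([10_000], [0], [0], ind="b")
        assert len(align_dyad(a, b, tol=60)) == 0

    @given(st.integers(1, 20), st.integers(1, 20), st.integers(0, 3))
    @settings(derandomize=True, max_examples=30)
    def test_output_never_longer_than_either_input(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        ta = np.sort(rng.choice(3000, size=na, replace=False)).astype(float)
        tb = np.sort(rng.choice(3000, size=nb, replace=False)).astype(float)
        a = mk_traj(ta, np.zeros(na), np.zeros(na))
        b = mk_traj(tb, np.zeros(nb), np.zeros(nb), ind="b")
        assert len(align_dyad(a, b, tol=100)) <= min(na, nb)


class TestPathLength:
    @pytest.mark.parametrize(
        "xs, ys, expected",
        [
            ([0, 3], [0, 4], 5.0),          # 3-4-5 triangle
            ([2], [7], 0.0),                # single fix
            ([0, 3, 3], [0, 4, 4], 5.0),    # zero-length step
        ],
    )
    def test_examples(self, xs, ys, expected):
        tr = mk_traj(range(len(xs)), xs, ys)
        assert path_length(tr) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=15),
           st.floats(0, 2 * np.pi), st.floats(-50, 50), st.floats(-50, 50))
    @settings(derandomize=True, max_examples=50)
    def test_rigid_motion_invariance(self, pts, theta, dx, dy):
        xs, ys = np.array(pts).T
        base = path_length(mk_traj(range(len(pts)), xs, ys))
        c, s = np.cos(theta), np.sin(theta)
        moved = path_length(
            mk_traj(range(len(pts)), c * xs - s * ys + dx, s * xs + c * ys + dy)
        )
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestValidationAndIO:
    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            mk_traj([0, 0], [0, 1], [0, 1])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            mk_traj([0, 1], [0, np.nan], [0, 1])

    def test_pool_nights_orders_by_time(self):
        n2 = mk_traj([100, 200], [2, 3], [0, 0], night="n2")
        n1 = mk_traj([0, 50], [0, 1], [0, 0], night="n1")
        pooled = pool_nights([n2, n1])
        assert pooled.night_id == "pooled"
        assert pooled.t.tolist() == [0, 50, 100, 200]

    def test_csv_missing_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("individual_id,sex,timestamp,x,y\na,M,2020-01-01T00:00:00,0,0\n")
        with pytest.raises(ValueError, match="night_id"):
            read_trajectories_csv(p)

    def test_csv_malformed_row_rejected_with_line_number(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        p.write_text(
            "individual_id,sex,night_id,timestamp,x,y\n"
            "a,M,n1,2020-01-01T00:00:00,0,0\n"
            "a,M,n1,not-a-time,1,1\n"
            "a,M,n1,2020-01-01T00:05:00,2,2\n"
        )
        with caplog.at_level("WARNING"):
            trajs = read_trajectories_csv(p)
        assert len(trajs) == 1 and len(trajs[0]) == 2
        assert "3" in caplog.text  # the offending line number
        assert trajs[0].in_sight.all()  # defaulted to True
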