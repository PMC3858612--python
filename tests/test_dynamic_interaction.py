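import numpy as np
import pytest
from scipy import stats

from conftest import dyad_from_distances
from pairspace.dynamic_interaction import (
    GasModelParams,
    doncaster_test,
    gas_expected_rate,
    hutchinson_expected,
    observed_encounters,
    proximity_time,
    wilcoxon_across_pairs,
)
from pairspace.trajectory_core import DyadSeries


class TestExpectedRates:
    def test_gas_closed_form(self):
        p = GasModelParams(rho=1 / 3000, v=500, s=0, d=15)
        assert gas_expected_rate(p) == pytest.approx(20 / np.pi)  # ~6.37

    def test_gas_vanishes_without_motion_or_reach(self):
        assert gas_expected_rate(GasModelParams(rho=1e-3, v=0, s=10, d=15)) == 0
        assert gas_expected_rate(GasModelParams(rho=1e-3, v=100, s=0, d=0)) == 0

    def test_hutchinson_closed_form(self):
        assert hutchinson_expected(100, 1 / 10_000, 15) == pytest.approx(
            100 * np.pi * 225 / 10_000
        )
        assert hutchinson_expected(0, 1 / 100, 15) == 0

    def test_linear_in_rho_monotone_in_d(self):
        base = GasModelParams(rho=1e-4, v=300, s=5, d=10)
        double = GasModelParams(rho=2e-4, v=300, s=5, d=10)
        assert gas_expected_rate(double) == pytest.approx(2 * gas_expected_rate(base))
        assert hutchinson_expected(50, 2e-4, 10) == pytest.approx(
            2 * hutchinson_expected(50, 1e-4, 10)
        )
        ds = np.linspace(0, 40, 9)
        gas = [gas_expected_rate(GasModelParams(rho=1e-4, v=300, s=5, d=d)) for d in ds]
        hutch = [hutchinson_expected(50, 1e-4, d) for d in ds]
        assert np.all(np.diff(gas) > 0) and np.all(np.diff(hutch) >= 0)

    def test_hutchinson_uniform_placement_oracle(self):
        # i.i.d.-uniform positions on a torus (no boundary): the observed
        # below-d count matches N*rho*pi*d^2
        L, d, n = 100.0, 15.0, 10_000
        rng = np.random.default_rng(0)
        a = rng.uniform(0, L, (n, 2))
        b = rng.uniform(0, L, (n, 2))
        diff = np.abs(a - b)
        diff = np.minimum(diff, L - diff)
        observed = (np.hypot(diff[:, 0], diff[:, 1]) <= d).sum()
        expected = hutchinson_expected(n, 1 / L**2, d)
        assert observed == pytest.approx(expected, rel=0.05)


class TestObservedEncounters:
    def test_identical_trajectories(self):
        dy = dyad_from_distances([0, 0, 0, 0])
        counts = observed_encounters(dy, d=5)
        assert counts.associations == 4 and counts.entries == 1

    def test_runs_counted_as_entries(self):
        counts = observed_encounters(dyad_from_distances([20, 10, 10, 20, 5]), d=15)
        assert counts.associations == 3 and counts.entries == 2

    def test_empty_series(self):
        empty = DyadSeries("m", "f", [], np.empty((0, 2)), np.empty((0, 2)))
        assert observed_encounters(empty, 15) == (0, 0)


class TestDoncaster:
    def brute_table(self, dy, d):
        n = len(dy)
        obs = sum(
            np.hypot(*(dy.male_xy[i] - dy.female_xy[i])) <= d for i in range(n)
        )
        allb = sum(
            np.hypot(*(dy.male_xy[i] - dy.female_xy[j])) <= d
            for i in range(n) for j in range(n)
        )
        return [[obs, n - obs], [allb, n * n - allb]]

    def test_table_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        dy = DyadSeries("m", "f", np.arange(25) * 60.0,
                        rng.uniform(0, 40, (25, 2)), rng.uniform(0, 40, (25, 2)))
        res = doncaster_test(dy, d=15, min_n=20)
        assert res.params["table"] == self.brute_table(dy, 15)
        ref = stats.chi2_contingency(res.params["table"], correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_positions_never_avoidance(self):
        xy = np.random.default_rng(8).uniform(0, 50, (30, 2))
        dy = DyadSeries("m", "f", np.arange(30) * 60.0, xy, xy.copy())
        res = doncaster_test(dy, d=15, min_n=20)
        assert res.direction in ("attraction", "none")
        assert res.observed == 30  # every simultaneous distance is zero

    def test_small_series_rejected(self):
        dy = dyad_from_distances([1.0] * 5)
        with pytest.raises(ValueError, match="at least"):
            doncaster_test(dy, d=15)

    def test_direction_avoidance_when_partners_alternate(self):
        # partners occupy the same two stations but always out of phase:
        # observed distances all exceed d while half of the cross pairings
        # fall below it
        n = 40
        male = np.array([[0.0, 0.0], [100.0, 0.0]] * (n // 2))
        female = np.array([[100.0, 0.0], [0.0, 0.0]] * (n // 2))
        dy = DyadSeries("m", "f", np.arange(n) * 60.0, male, female)
        res = doncaster_test(dy, d=15)
        assert res.direction == "avoidance"
        assert res.observed == 0 and res.expected == pytest.approx(n / 2)


class TestProximityAndWilcoxon:
    def test_identical_trajectories_full_proximity(self):
        assert proximity_time(dyad_from_distances([0, 0, 0]), d=1) == 100.0

    def test_quarter_share(self):
        assert proximity_time(dyad_from_distances([5, 25, 25, 25]), d=10) == 25.0

    def test_empty_rejected(self):
        empty = DyadSeries("m", "f", [], np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            proximity_time(empty, 10)

    def test_wilcoxon_wrapper_on_one_signed_differences(self):
        observed = [10, 12, 9, 14, 11, 13, 15]
        expected = [5, 6, 4, 7, 5, 6, 8]
        res = wilcoxon_across_pairs(observed, expected)
        assert res.statistic == 28 and res.p_two_sided == pytest.approx(2 / 128)
        with pytest.raises(ValueError):
            wilcoxon_across_pairs([1, 2], [1, 2, 3])
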