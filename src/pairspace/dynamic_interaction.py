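"""Dyadic dynamic-interaction tests: do pair partners attract, avoid, or
move independently?

Three complementary approaches are implemented for a male-female dyad
followed simultaneously:

* **Random gas model** — expected encounter rate between two independently
  moving animals, ``f = (4 rho v / pi) * (2 d + s)``, with ``rho`` the pair
  density (1 / union home-range area in m^2), ``v`` the distance covered per
  observation period (m), ``s`` the group spread and ``d`` the distance
  criterion (both m).
* **Hutchinson's model** — the correction for instantaneous point samples,
  ``f = N rho pi d^2`` expected associations among ``N`` simultaneous fixes.
* **Doncaster's test** — a per-dyad contingency test: the N observed
  simultaneous inter-partner distances are classified below/above ``d`` and
  compared against all N^2 cross-pairings of the same two point sets with a
  df=1 chi-squared test.

An *association* is an aligned time point with inter-partner distance <= d;
an *encounter* (for the rate comparison against the gas model) is an entry
into the below-d state, i.e. a maximal run of consecutive associations
counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist

from . import exact_stats
from .trajectory_core import DyadSeries, Trajectory, path_length
from .home_range_kde import RangePolygon

__all__ = [
    "GasModelParams",
    "DyadTestResult",
    "EncounterCounts",
    "gas_expected_rate",
    "hutchinson_expected",
    "observed_encounters",
    "doncaster_test",
    "proximity_time",
    "wilcoxon_across_pairs",
    "gas_params_for_dyad",
    "DEFAULT_DISTANCE_CRITERION_M",
]

#: Distance criterion (m) defining an association/encounter — close enough
#: for visual contact between partners in this habitat.
DEFAULT_DISTANCE_CRITERION_M = 15.0
#: Default group spread (m); the focal animals forage solitarily.
DEFAULT_GROUP_SPREAD_M = 0.0


@dataclass
class GasModelParams:
    """Inputs of the ideal-gas encounter model.

    rho: pair density per m^2 (inverse of the pair's union home-range area);
    v: distance covered per observation period (m), averaged over partners;
    s: group spread (m); d: distance criterion (m).
    """

    rho: float
    v: float
    s: float = DEFAULT_GROUP_SPREAD_M
    d: float = DEFAULT_DISTANCE_CRITERION_M

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.v < 0 or self.s < 0 or self.d < 0:
            raise ValueError("v, s, d must be nonnegative")


@dataclass
class DyadTestResult:
    model: str
    observed: float
    expected: float
    statistic: float | None
    p_value: float | None
    direction: str  # attraction | avoidance | none
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValueError("observed and expected must be nonnegative")
        if self.p_value is not None and not 0 < self.p_value <= 1:
            raise ValueError("p out of (0, 1]")


class EncounterCounts(NamedTuple):
    associations: int  # aligned points with distance <= d
    entries: int       # maximal below-d runs (entries into proximity)


def gas_expected_rate(p: GasModelParams) -> float:
    """Expected encounters per observation period under the random gas model."""
    return 4 * p.rho * p.v / np.pi * (2 * p.d + p.s)


def hutchinson_expected(n_obs: int, rho: float, d: float) -> float:
    """Expected associations among ``n_obs`` instantaneous point samples."""
    if n_obs < 0:
        raise ValueError("N must be nonnegative")
    return n_obs * rho * np.pi * d**2


def observed_encounters(dy: DyadSeries, d: float = DEFAULT_DISTANCE_CRITERION_M) -> EncounterCounts:
    """Count associations (below-d points) and encounters (below-d entries)."""
    if d < 0:
        raise ValueError("d must be nonnegative")
    if len(dy) == 0:
        return EncounterCounts(0, 0)
    below = dy.distances() <= d
    associations = int(below.sum())
    entries = int(below[0]) + int(np.count_nonzero(below[1:] & ~below[:-1]))
    return EncounterCounts(associations, entries)


def doncaster_test(dy: DyadSeries, d: float = DEFAULT_DISTANCE_CRITERION_M,
                   alpha: float = 0.05, min_n: int = 20,
                   correction: bool = False) -> DyadTestResult:
    """Contingency test of the N observed distances against all N^2 pairings.

    The 2x2 table rows are {observed N pairings, all N^2 cross pairings}
    (the observed pairings are part of the N^2 set) and columns {<=d, >d}.
    Direction is attraction when the observed below-d proportion exceeds the
    cross-pairing proportion and the chi-squared p-value is <= alpha,
    avoidance when it is lower, and none otherwise.
    """
    n = len(dy)
    if n < min_n:
        raise ValueError(f"need at least {min_n} aligned fixes (got {n})")
    obs_below = int((dy.distances() <= d).sum())
    cross = cdist(dy.male_xy, dy.female_xy)
    all_below = int((cross <= d).sum())
    table = [[obs_below, n - obs_below], [all_below, n * n - all_below]]
    res = exact_stats.chi2_independence_2x2(table, correction=correction)
    p_obs = obs_below / n
    p_all = all_below / (n * n)
    if res.p_two_sided > alpha or p_obs == p_all:
        direction = "none"
    else:
        direction = "attraction" if p_obs > p_all else "avoidance"
    return DyadTestResult(
        model="doncaster",
        observed=obs_below,
        expected=n * p_all,
        statistic=res.statistic,
        p_value=res.p_two_sided,
        direction=direction,
        params={"d": d, "N": n, "alpha": alpha, "table": table},
    )


def proximity_time(dy: DyadSeries, d: float) -> float:
    """Percent of aligned time points the partners spent within ``d`` meters."""
    if len(dy) == 0:
        raise ValueError("empty dyad series")
    return 100.0 * float((dy.distances() <= d).mean())


def wilcoxon_across_pairs(observed, expected) -> exact_stats.TestResult:
    """Exact signed-rank test of per-pair observed vs expected values."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    return exact_stats.signed_rank_exact(observed - expected)


def gas_params_for_dyad(male_range: RangePolygon, female_range: RangePolygon,
                        male_nights: list[Trajectory], female_nights: list[Trajectory],
                        d: float = DEFAULT_DISTANCE_CRITERION_M,
                        s: float = DEFAULT_GROUP_SPREAD_M) -> GasModelParams:
    """Gas-model parameters from a dyad's data.

    ``rho`` is the inverse of the pair's union home-range area (polygon
    union of the two ranges, m^2); ``v`` is the mean over partners of the
    mean nightly path length (m per observation period).
    """
    union_area = male_range.geometry.union(female_range.geometry).area
    if union_area <= 0:
        raise ValueError("union home range has zero area")
    v_m = float(np.mean([path_length(tr) for tr in male_nights]))
    v_f = float(np.mean([path_length(tr) for tr in female_nights]))
    return GasModelParams(rho=1.0 / union_area, v=(v_m + v_f) / 2.0, s=s, d=d)
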