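"""Synthetic dyadic telemetry with the statistical structure the analysis
assumes: stationary individual home ranges, tunable partner
attraction/avoidance, sleeping-site records, and interaction events.

Movement model
--------------
Each animal follows a discrete Ornstein-Uhlenbeck (OU) walk toward its own
range center ``c``:

    x_{t+1} = x_t + a (c - x_t) + eta * u_t * 1[dist < R] + e_t,
    e_t ~ N(0, step_sd^2 I)

where ``a`` is the mean-reversion fraction per fix interval and ``u_t`` the
unit vector toward the partner. The coupling ``eta`` (m per step) is applied
only within the perception radius ``R``: eta > 0 is attraction, eta < 0
avoidance, 0 independence. The OU choice makes ranges stationary and
analytically checkable: per-axis stationary variance is
``step_sd^2 / (1 - (1-a)^2)``, so the 95% utilization area of an uncoupled
animal is ``pi * chi2_2(0.95) * sigma_st^2``. By default ``step_sd`` is
derived from the requested 95%-range radius through that relation.

The default configuration mirrors the field design the package targets:
seven male-female dyads, dusk-to-dawn follows of ~10.5 h, 60-s raw fixes
(subsampled to 5 min downstream), eight follow nights per dyad, female 95%
ranges of ~0.18 ha and male ~0.33 ha, pair partners sharing a range center
while neighboring pairs are spaced far enough apart for near-zero same-sex
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory_core import DyadSeries, Trajectory

__all__ = ["SimConfig", "StudyData", "simulate_dyad", "simulate_social",
           "simulate_study", "preset_paper", "stationary_sd"]

CHI2_2_95 = 5.991464547107979  # chi-squared(2) quantile at 0.95

#: Study epoch: seconds are measured from this instant (18:00 local dusk).
STUDY_EPOCH = pd.Timestamp("2011-10-01T18:00:00")


def _r95_to_sd(r95_m: float) -> float:
    """Stationary per-axis SD whose analytic 95% area matches radius r95."""
    return r95_m / np.sqrt(CHI2_2_95)


@dataclass
class SimConfig:
    """Simulator configuration; defaults are the study-shaped conditions."""

    seed: int = 0
    n_dyads: int = 7
    nights_per_dyad: int = 8
    night_duration_h: float = 10.5
    fix_interval_s: float = 60.0
    #: distance between the centers of neighboring pairs (m)
    pair_spacing_m: float = 80.0
    #: 95% home-range radius (m); male > female
    male_r95_m: float = 32.4   # ~0.33 ha
    female_r95_m: float = 23.9  # ~0.18 ha
    #: OU mean-reversion fraction per fix interval
    mean_reversion: float = 0.05
    #: per-step noise SD (m); None derives it from the range radii
    step_sd_m: float | None = None
    #: partner coupling eta (m per step): <0 avoidance, 0 independence
    coupling: float = 0.0
    perception_radius_m: float = 30.0
    # sleeping-site generator
    obs_days: int = 60
    n_exclusive_trees_m: int = 6
    n_exclusive_trees_f: int = 4
    n_shared_trees: int = 3
    p_shared_tree: float = 0.3
    p_simultaneous: float = 0.0
    # interaction generator (events per in-sight hour)
    hours_in_sight_per_dyad: float = 73.7  # 516 h over 7 dyads
    rate_neutral: float = 0.11
    rate_agonistic: float = 0.03
    rate_affiliative: float = 0.005

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.nights_per_dyad < 1:
            raise ValueError("need at least one dyad and one night")
        if self.night_duration_h <= 0 or self.fix_interval_s <= 0:
            raise ValueError("night duration and fix interval must be positive")
        if self.male_r95_m <= 0 or self.female_r95_m <= 0:
            raise ValueError("range radii must be positive")
        if not 0 < self.mean_reversion < 1:
            raise ValueError("mean_reversion must be in (0, 1)")
        if self.perception_radius_m < 0:
            raise ValueError("perception radius must be nonnegative")
        if not 0 <= self.p_simultaneous <= 1 or not 0 <= self.p_shared_tree <= 1:
            raise ValueError("probabilities must be in [0, 1]")

    def stationary_sds(self) -> tuple[float, float]:
        """(male, female) per-axis stationary SDs implied by the radii."""
        return _r95_to_sd(self.male_r95_m), _r95_to_sd(self.female_r95_m)

    def step_sds(self) -> tuple[float, float]:
        """(male, female) per-step noise SDs."""
        shrink = np.sqrt(1.0 - (1.0 - self.mean_reversion) ** 2)
        if self.step_sd_m is not None:
            return self.step_sd_m, self.step_sd_m
        sm, sf = self.stationary_sds()
        return sm * shrink, sf * shrink

    def pair_center(self, dyad_index: int) -> np.ndarray:
        """Shared range center of a pair; pairs sit on a line."""
        return np.array([dyad_index * self.pair_spacing_m, 0.0])


def stationary_sd(step_sd: float, mean_reversion: float) -> float:
    """Per-axis stationary SD of the uncoupled OU walk."""
    return step_sd / np.sqrt(1.0 - (1.0 - mean_reversion) ** 2)


@dataclass
class StudyData:
    """Bundle of one simulated study."""

    config: SimConfig
    trajectories: list[Trajectory]          # per individual per night
    dyads: pd.DataFrame                     # male_id, female_id, hours_in_sight
    dyad_series: dict[str, DyadSeries]      # key "maleid-femaleid", pooled
    sleeping: pd.DataFrame                  # date, individual_id, tree_id
    interactions: pd.DataFrame              # timestamp, actor_id, receiver_id, codes, distance_m

    def nights_of(self, individual_id: str) -> list[Trajectory]:
        return [tr for tr in self.trajectories if tr.individual_id == individual_id]


def _simulate_pair_walk(rng: np.random.Generator, cfg: SimConfig,
                        center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coupled OU walk for one dyad, batched over nights.

    Returns male and female position arrays of shape
    (nights, steps_per_night, 2); each night starts from an independent
    stationary draw.
    """
    a = cfg.mean_reversion
    sd_m, sd_f = cfg.stationary_sds()
    step_m, step_f = cfg.step_sds()
    eta = cfg.coupling
    radius = cfg.perception_radius_m
    nights = cfg.nights_per_dyad
    n_steps = int(round(cfg.night_duration_h * 3600.0 / cfg.fix_interval_s)) + 1

    m = center + rng.standard_normal((nights, 2)) * sd_m
    f = center + rng.standard_normal((nights, 2)) * sd_f
    M = np.empty((nights, n_steps, 2))
    F = np.empty((nights, n_steps, 2))
    for t in range(n_steps):
        M[:, t] = m
        F[:, t] = f
        if t == n_steps - 1:
            break
        dvec = f - m  # male -> female
        dist = np.hypot(dvec[:, 0], dvec[:, 1])
        near = (dist < radius) & (dist > 0)
        u = np.zeros_like(dvec)
        u[near] = dvec[near] / dist[near, None]
        m = m + a * (center - m) + eta * u + step_m * rng.standard_normal((nights, 2))
        f = f + a * (center - f) - eta * u + step_f * rng.standard_normal((nights, 2))
    return M, F


def _night_times(cfg: SimConfig, night: int) -> np.ndarray:
    n_steps = int(round(cfg.night_duration_h * 3600.0 / cfg.fix_interval_s)) + 1
    t0 = night * 86400.0
    return t0 + cfg.fix_interval_s * np.arange(n_steps)


def simulate_dyad(cfg: SimConfig, dyad_index: int = 0
                  ) -> tuple[list[tuple[Trajectory, Trajectory]], DyadSeries]:
    """Simulate one dyad: per-night (male, female) trajectories plus the
    pooled aligned series. Deterministic given (cfg.seed, dyad_index)."""
    rng = np.random.default_rng([int(cfg.seed), 1000 + dyad_index])
    center = cfg.pair_center(dyad_index)
    M, F = _simulate_pair_walk(rng, cfg, center)
    male_id = f"m{dyad_index + 1}"
    female_id = f"f{dyad_index + 1}"
    nights = []
    parts = []
    for k in range(cfg.nights_per_dyad):
        t = _night_times(cfg, dyad_index * cfg.nights_per_dyad + k)
        night_id = f"d{dyad_index + 1}n{k + 1}"
        tr_m = Trajectory(male_id, t, M[k, :, 0], M[k, :, 1], sex="M", night_id=night_id)
        tr_f = Trajectory(female_id, t, F[k, :, 0], F[k, :, 1], sex="F", night_id=night_id)
        nights.append((tr_m, tr_f))
        parts.append(DyadSeries(male_id, female_id, t, M[k], F[k]))
    return nights, DyadSeries.concat(parts)


def simulate_social(cfg: SimConfig, dyads: list[tuple[str, str]]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sleeping records and interaction events for the given dyads.

    Sleeping: one tree per individual per day, drawn from the dyad's pool
    (exclusive and shared trees); with probability ``p_simultaneous`` the
    partners deliberately share the same tree that day, otherwise they never
    do. Interactions: an independent Poisson process per class over the
    dyad's in-sight hours, with class-consistent distances and codes.
    """
    rng = np.random.default_rng([int(cfg.seed), 2])
    sleep_rows = []
    event_rows = []
    agonistic_codes = ["chase", "charge", "bite", "grab", "flee", "displace", "jump_away"]
    for i, (male, female) in enumerate(dyads):
        shared = [f"d{i + 1}_S{k}" for k in range(cfg.n_shared_trees)]
        excl_m = [f"d{i + 1}_M{k}" for k in range(cfg.n_exclusive_trees_m)]
        excl_f = [f"d{i + 1}_F{k}" for k in range(cfg.n_exclusive_trees_f)]
        dates = pd.date_range(STUDY_EPOCH.normalize(), periods=cfg.obs_days, freq="D")
        for date in dates:
            if shared and rng.random() < cfg.p_simultaneous:
                tree = shared[rng.integers(len(shared))]
                tree_m = tree_f = tree
            else:
                def draw(shared_pool, excl_pool, avoid=None):
                    for _ in range(100):
                        pool = shared_pool if (shared_pool and rng.random() < cfg.p_shared_tree) else excl_pool
                        tree = pool[rng.integers(len(pool))]
                        if tree != avoid:
                            return tree
                    raise RuntimeError("could not draw a distinct sleeping tree")
                tree_m = draw(shared, excl_m)
                tree_f = draw(shared, excl_f, avoid=tree_m)
            day = date.strftime("%Y-%m-%d")
            sleep_rows.append({"date": day, "individual_id": male, "tree_id": tree_m})
            sleep_rows.append({"date": day, "individual_id": female, "tree_id": tree_f})
        # interaction events
        hours = cfg.hours_in_sight_per_dyad
        for klass, rate in (("neutral", cfg.rate_neutral),
                            ("agonistic", cfg.rate_agonistic),
                            ("affiliative", cfg.rate_affiliative)):
            n_events = rng.poisson(rate * hours)
            for _ in range(n_events):
                t = STUDY_EPOCH + pd.to_timedelta(rng.uniform(0, hours * 3600), unit="s")
                actor, receiver = (male, female) if rng.random() < 0.5 else (female, male)
                if klass == "agonistic":
                    codes = agonistic_codes[rng.integers(len(agonistic_codes))]
                    dist = rng.uniform(0, 5)
                elif klass == "affiliative":
                    codes = "groom" if rng.random() < 0.5 else ""
                    dist = rng.uniform(0, 1)
                else:
                    codes = ""
                    dist = rng.uniform(1.001, 5)
                event_rows.append(
                    {
                        "timestamp": t.strftime("%Y-%m-%dT%H:%M:%S"),
                        "actor_id": actor,
                        "receiver_id": receiver,
                        "codes": codes,
                        "distance_m": round(dist, 2),
                    }
                )
    sleeping = pd.DataFrame(sleep_rows)
    interactions = pd.DataFrame(
        event_rows, columns=["timestamp", "actor_id", "receiver_id", "codes", "distance_m"]
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)
    return sleeping, interactions


def simulate_study(cfg: SimConfig) -> StudyData:
    """Simulate the full multi-dyad study bundle."""
    trajectories: list[Trajectory] = []
    series: dict[str, DyadSeries] = {}
    dyad_rows = []
    dyad_ids = []
    for i in range(cfg.n_dyads):
        nights, dy = simulate_dyad(cfg, i)
        for tr_m, tr_f in nights:
            trajectories.extend([tr_m, tr_f])
        series[f"{dy.male_id}-{dy.female_id}"] = dy
        dyad_rows.append(
            {
                "male_id": dy.male_id,
                "female_id": dy.female_id,
                "hours_in_sight": cfg.hours_in_sight_per_dyad,
            }
        )
        dyad_ids.append((dy.male_id, dy.female_id))
    sleeping, interactions = simulate_social(cfg, dyad_ids)
    return StudyData(cfg, trajectories, pd.DataFrame(dyad_rows), series, sleeping, interactions)


def preset_paper(seed: int = 0, **overrides) -> SimConfig:
    """Study-shaped preset: seven avoiding dyads.

    Radii and coupling are jointly calibrated so that the measured 95%
    kernel areas land near 0.33 ha (males) and 0.18 ha (females) — the
    nominal radii are set below the analytic uncoupled values because both
    kernel smoothing and the repulsive coupling inflate the realized range —
    and pair partners spend on the order of 5% of aligned time within 10 m
    and ~24% within 20 m, with the Doncaster contingency test flagging
    avoidance for all seven dyads.
    """
    params = dict(
        seed=seed,
        coupling=-0.55,
        perception_radius_m=40.0,
        male_r95_m=28.0,
        female_r95_m=20.5,
    )
    params.update(overrides)
    return SimConfig(**params)
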