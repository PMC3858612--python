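import numpy as np
import pytest

from pairspace.trajectory_core import DyadSeries, Trajectory


def mk_traj(times, xs, ys, ind="a", sex="?", night="n1", in_sight=None):
    return Trajectory(ind, np.asarray(times, float), np.asarray(xs, float),
                      np.asarray(ys, float), sex=sex, night_id=night, in_sight=in_sight)


def dyad_from_distances(distances):
    """DyadSeries with the male at the origin and the female at the given
    inter-partner distances along x, one fix per minute."""
    d = np.asarray(distances, float)
    t = 60.0 * np.arange(d.size)
    male = np.zeros((d.size, 2))
    female = np.column_stack([d, np.zeros(d.size)])
    return DyadSeries("m", "f", t, male, female)


@pytest.fixture(scope="session")
def gaussian_cloud():
    """10,000 seeded standard-bivariate-normal points."""
    return np.random.default_rng(0).standard_normal((10_000, 2))
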