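import datetime as dt

import numpy as np
import pytest

import phenorisk as pr


@pytest.fixture(scope="session")
def epos():
    """Light brown apple moth parameters (overwintering larva)."""
    return pr.load_bundled_species("epiphyas_postvittana")


@pytest.fixture(scope="session")
def nele():
    """Small tomato borer parameters (overwintering adult)."""
    return pr.load_bundled_species("neoleucinodes_elegantalis")


def constant_cube(temp, n_days=365, n_rows=1, n_cols=1,
                  start=dt.date(2018, 1, 1)):
    """WeatherCube at a constant temperature (tmin = tmax = temp)."""
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    arr = np.full((n_days, n_rows, n_cols), float(temp))
    geom = pr.GridGeometry(x0=-100.0, y0=45.0, dx=0.25, dy=0.25)
    return pr.WeatherCube(dates=dates, tmin=arr.copy(), tmax=arr.copy(),
                          geometry=geom)


def triangle_oracle(tmin, tmax, ldt, udt, n_minutes=1440):
    """Independent single-triangle oracle: 1-minute numeric integration.

    The day is a triangular trajectory from tmin up to tmax and back;
    degree-days are the time-average of the trajectory clipped to
    [ldt, udt], minus ldt. Vectorized over leading axes of the inputs.
    """
    tmin = np.atleast_1d(np.asarray(tmin, dtype=float))[..., None]
    tmax = np.atleast_1d(np.asarray(tmax, dtype=float))[..., None]
    t = (np.arange(n_minutes) + 0.5) / n_minutes * 24.0
    up = tmin + (tmax - tmin) * t / 12.0
    down = tmax - (tmax - tmin) * (t - 12.0) / 12.0
    temp = np.where(t <= 12.0, up, down)
    vals = np.clip(temp, ldt, udt) - ldt
    out = vals.mean(axis=-1)
    return float(out[0]) if out.size == 1 else out


@pytest.fixture(scope="session")
def gradient_run(epos):
    """Default synthetic north-south gradient cube and its untiled run."""
    cube = pr.generate(pr.SynthSpec())
    config = pr.RunConfig(n_cohorts=7, sample_every=30)
    return cube, config, pr.run_grid(cube, epos, config)
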