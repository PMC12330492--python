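"""Direct (unsplit) brute-force simulation utilities.

These run ordinary ensembles of independent walkers with the same
iteration semantics as the weighted-ensemble engine — propagation in
tau-length segments, end-of-segment checks for sink arrival and
upper-boundary recycling — but with no binning, splitting or merging.
They serve as independent cross-checks of the WE kinetics (mean first
passage times) and are deliberately kept free of any WE machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import units
from .landscape import ToyLandscape, _step_batch
from .titration import neutral_fraction

__all__ = ["FirstPassageResult", "direct_mfpt"]


@dataclass
class FirstPassageResult:
    """Sample of first passage times from direct simulation."""

    fpt_s: np.ndarray  # first passage times in seconds
    mfpt: float  # s
    interval: tuple[float, float]  # 95% t-interval on the mean, s
    n_censored: int  # walkers that never arrived within max_time


def direct_mfpt(
    landscape: ToyLandscape,
    n_walkers: int = 64,
    tau: float = 100.0,
    dt: float = 10.0,
    pH: float = 7.5,
    seed: int = 0,
    source_z: float = 30.0,
    sink_z: float = -20.0,
    recycle_upper: float = 55.0,
    max_time: float = 1e8,
    z_walls: tuple[float, float] = (-30.0, 60.0),
) -> FirstPassageResult:
    """Mean first passage time from the source into the intracellular state.

    Each walker starts at ``source_z`` with λ drawn from the solution
    equilibrium, and is checked every ``tau`` ps: crossing ``sink_z``
    counts as arrival; exceeding ``recycle_upper`` resets the walker to the
    source (the steady-state recycling convention).  The 95% interval is
    the t-interval on the sample mean.
    """
    rng = np.random.default_rng(seed)
    f_src = neutral_fraction(landscape.solution_pKa, pH)
    z = np.full(n_walkers, float(source_z))
    lam = (rng.random(n_walkers) < f_src).astype(float)
    alive = np.arange(n_walkers)
    fpt = np.full(n_walkers, np.nan)
    n_steps = int(round(tau / dt))
    t = 0.0
    while alive.size and t < max_time:
        z_a, lam_a = _step_batch(
            z[alive], lam[alive], landscape, pH, dt, n_steps, rng, *z_walls
        )
        t += tau
        arrived = z_a < sink_z
        fpt[alive[arrived]] = t
        reset = z_a > recycle_upper
        z_a[reset] = source_z
        lam_a[reset] = (rng.random(int(reset.sum())) < f_src).astype(float)
        z[alive], lam[alive] = z_a, lam_a
        alive = alive[~arrived]
    done = np.isfinite(fpt)
    fpt_s = fpt[done] * units.PS_TO_S
    n = fpt_s.size
    if n == 0:
        return FirstPassageResult(fpt_s, math.inf, (math.inf, math.inf), n_walkers)
    mean = float(fpt_s.mean())
    if n > 1:
        half = float(stats.t.ppf(0.975, n - 1) * fpt_s.std(ddof=1) / math.sqrt(n))
    else:
        half = math.inf
    return FirstPassageResult(
        fpt_s=fpt_s,
        mfpt=mean,
        interval=(mean - half, mean + half),
        n_censored=int(n_walkers - n),
    )
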