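"""Flux-derived kinetics: permeability, MFPT, intervals and run comparison.

The steady-state probability flux from the extracellular to the
intracellular macrostate, f_ex→in (1/s), yields the effective
permeability and mean first passage time

    Pm   = f_ex→in · ld        (ld: depth of the effective reaction volume)
    MFPT = p_ext / f_ex→in

with p_ext the weight fraction of trajectories whose most recently
visited macrostate is extracellular (1 in a source–sink setup).  The
95% intervals are propagated from mean ± 1.96·SE of the flux, computed
on the flux scale over the analysis window.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import units
from .errors import ConfigError, PermweightError, UndefinedRateError
from .we import IterationRecord, _LIN_EXT, _LIN_INT

__all__ = [
    "FluxEstimate",
    "flux_series",
    "estimate",
    "compare_runs",
    "deprotonation_rate",
    "p_ext_from_lineage",
]

#: Default depth of the effective reaction volume, Å (half the water buffer).
DEFAULT_LD = 22.5


@dataclass
class FluxEstimate:
    """Flux → permeability → MFPT chain with 95% intervals."""

    flux_mean: float  # 1/s
    flux_se: float  # 1/s
    ld: float  # Å
    p_ext: float
    Pm: float  # cm/s
    log10_Pm: float
    MFPT: float  # s
    interval_log10_Pm: tuple[float, float]
    interval_MFPT: tuple[float, float]
    window: tuple[int, int]
    n_iterations: int
    no_permeation_events: bool = False
    interval_convention: str = "normal 1.96 SE on the flux scale, transformed"

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def flux_series(records: Sequence[IterationRecord]) -> np.ndarray:
    """Per-iteration extracellular→intracellular flux in 1/s.

    Element i is the weight newly entering the intracellular macrostate in
    iteration i divided by the iteration time tau.
    """
    if len(records) == 0:
        raise ConfigError("records must be nonempty")
    taus = np.array([r.tau for r in records], dtype=float)
    if np.any(taus <= 0):
        raise ConfigError("iteration tau must be positive")
    w = np.array([r.new_intracellular_weight for r in records], dtype=float)
    return w / (taus * units.PS_TO_S)


def estimate(
    flux: Sequence[float] | np.ndarray,
    ld: float = DEFAULT_LD,
    p_ext: float = 1.0,
    window: int | None = 50,
) -> FluxEstimate:
    """Point estimate and 95% interval of Pm and MFPT from a flux series.

    ``window`` selects the last n iterations (None = all).  A zero mean
    flux yields Pm = 0 and MFPT = +inf with the ``no_permeation_events``
    flag set, mirroring runs in which the permeant never reaches the far
    leaflet.
    """
    flux = np.asarray(flux, dtype=float)
    if np.any(flux < 0):
        raise PermweightError("negative flux values: data integrity failure")
    n_total = flux.size
    if window is not None:
        if window < 1:
            raise ConfigError("window must be >= 1")
        flux = flux[-window:]
    if flux.size == 0:
        raise ConfigError("empty analysis window")
    lo_idx = n_total - flux.size
    mean = float(flux.mean())
    se = float(flux.std(ddof=1) / math.sqrt(flux.size)) if flux.size > 1 else 0.0
    ld_cm = ld * units.ANGSTROM_TO_CM
    if mean == 0.0:
        return FluxEstimate(
            flux_mean=0.0,
            flux_se=se,
            ld=ld,
            p_ext=p_ext,
            Pm=0.0,
            log10_Pm=-math.inf,
            MFPT=math.inf,
            interval_log10_Pm=(-math.inf, -math.inf),
            interval_MFPT=(math.inf, math.inf),
            window=(lo_idx, n_total),
            n_iterations=flux.size,
            no_permeation_events=True,
        )
    flux_lo = max(mean - 1.96 * se, 0.0)
    flux_hi = mean + 1.96 * se

    def _log10_pm(f):
        return math.log10(f * ld_cm) if f > 0 else -math.inf

    def _mfpt(f):
        return p_ext / f if f > 0 else math.inf

    return FluxEstimate(
        flux_mean=mean,
        flux_se=se,
        ld=ld,
        p_ext=p_ext,
        Pm=mean * ld_cm,
        log10_Pm=_log10_pm(mean),
        MFPT=_mfpt(mean),
        interval_log10_Pm=(_log10_pm(flux_lo), _log10_pm(flux_hi)),
        interval_MFPT=(_mfpt(flux_hi), _mfpt(flux_lo)),
        window=(lo_idx, n_total),
        n_iterations=flux.size,
    )


def compare_runs(flux_a, flux_b) -> float:
    """Two-sided Welch t-test p-value between two flux series.

    Convention: if both series have zero variance, p = 1 for equal means
    and p = 0 otherwise.
    """
    a = np.asarray(flux_a, dtype=float)
    b = np.asarray(flux_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("both flux series need length >= 2")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def deprotonation_rate(
    records: Sequence[IterationRecord], window: int | None = None
) -> float:
    """In-bilayer deprotonation rate, 1/s.

    Weight flux from the (bilayer, protonated) to the (bilayer,
    deprotonated) state — states thresholded at λ < 0.2 and λ > 0.8 —
    measured with the same lineage-flux machinery as the macrostate flux,
    averaged over the analysis window.
    """
    if len(records) == 0:
        raise ConfigError("records must be nonempty")
    occupancy = 0.0
    for r in records:
        in_bilayer = np.abs(r.walkers.z) < 20.0
        occupancy += float(r.walkers.weight[in_bilayer].sum())
    if occupancy == 0.0:
        raise UndefinedRateError("no bilayer occupancy: deprotonation rate undefined")
    recs = records if window is None else records[-window:]
    w = np.array([r.new_deprotonated_weight for r in recs], dtype=float)
    taus = np.array([r.tau for r in recs], dtype=float)
    return float(np.mean(w / (taus * units.PS_TO_S)))


def p_ext_from_lineage(records: Sequence[IterationRecord]) -> float:
    """Weight fraction of walkers whose last-visited macrostate is
    extracellular, among walkers with any macrostate history (final
    iteration).  Returns 1.0 when no walker has a history yet (the
    source–sink convention)."""
    if len(records) == 0:
        raise ConfigError("records must be nonempty")
    t = records[-1].walkers
    w_ext = float(t.weight[t.lineage == _LIN_EXT].sum())
    w_int = float(t.weight[t.lineage == _LIN_INT].sum())
    if w_ext + w_int == 0.0:
        return 1.0
    return w_ext / (w_ext + w_int)
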