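"""Continuous titration coordinate and Henderson–Hasselbalch computations.

In constant-pH λ-dynamics each titratable site carries a fictitious
coordinate θ with λ = sin²θ ∈ [0, 1]; λ ≈ 0 is the protonated (charged
amine) state and λ ≈ 1 the deprotonated (neutral) state.  The model
compound is parameterized by a quadratic potential of mean force
U(λ) = A·(λ − B)², whose two parameters are obtained by thermodynamic
integration: mean forces ⟨∂U/∂θ⟩ computed at a grid of fixed θ values are
fitted to the analytic derivative ∂U/∂θ = 2A·(sin²θ − B)·sin 2θ.  The fit
is carried out in θ-space, where it is linear in (A, A·B).

Solution titration is summarized by the generalized Henderson–Hasselbalch
(Hill) curve

    f_deprot(pH) = 1 / (1 + 10^{n·(pKa − pH)}),

with n = 1 recovering the classic single-site form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import NoTransitionError, SingularFitError

__all__ = [
    "CANONICAL_THETA_GRID",
    "TitrationModel",
    "TitrationCurve",
    "lambda_from_theta",
    "fit_pmf_from_ti",
    "fit_henderson_hasselbalch",
    "neutral_fraction",
    "classify_state",
]

#: Fixed-θ grid (radians) conventionally used for the TI mean-force fit.
CANONICAL_THETA_GRID = (0.2, 0.4, 0.6, 0.7854, 1.0, 1.2, 1.4)


@dataclass
class TitrationModel:
    """Parameters of one titratable site.

    Parameters
    ----------
    model_pKa
        Solution pKa of the model compound (dimensionless).
    hill_n
        Hill coefficient of the generalized Henderson–Hasselbalch curve.
    pmf_A
        Curvature of the quadratic λ-PMF, kcal/mol.
    pmf_B
        Center of the quadratic λ-PMF (dimensionless, in λ units).
    lambda_lo, lambda_hi
        State-classification thresholds: λ < lambda_lo is protonated,
        λ > lambda_hi is deprotonated, anything between is mixed.
    """

    model_pKa: float
    hill_n: float = 1.0
    pmf_A: float = 0.0
    pmf_B: float = 0.0
    lambda_lo: float = 0.2
    lambda_hi: float = 0.8

    def __post_init__(self) -> None:
        if not math.isfinite(self.model_pKa):
            raise ValueError("model_pKa must be finite")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if not (0.0 <= self.lambda_lo < self.lambda_hi <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 <= lambda_lo < lambda_hi <= 1"
            )


@dataclass
class TitrationCurve:
    """Deprotonated fraction measured at a series of pH values."""

    ph_values: np.ndarray
    deprotonated_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.deprotonated_fractions = np.asarray(
            self.deprotonated_fractions, dtype=float
        )
        if self.ph_values.shape != self.deprotonated_fractions.shape:
            raise ValueError("pH and fraction arrays must have the same length")
        if self.ph_values.ndim != 1:
            raise ValueError("titration curve data must be one-dimensional")
        if not np.all(np.diff(self.ph_values) > 0):
            raise ValueError("pH values must be strictly increasing")
        f = self.deprotonated_fractions
        if np.any((f < 0) | (f > 1)):
            raise ValueError("deprotonated fractions must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"pH": self.ph_values, "fraction_deprotonated": self.deprotonated_fractions}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationCurve":
        df = pd.read_csv(path)
        return cls(df["pH"].to_numpy(), df["fraction_deprotonated"].to_numpy())


def lambda_from_theta(theta):
    """Map the internal coordinate θ (radians) to λ = sin²θ ∈ [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    lam = np.sin(theta) ** 2
    return float(lam) if lam.ndim == 0 else lam


def fit_pmf_from_ti(
    theta_grid: Sequence[float], mean_forces: Sequence[float]
) -> tuple[float, float]:
    """Fit the quadratic λ-PMF U(λ) = A(λ − B)² to TI mean forces.

    The mean force at fixed θ is ∂U/∂θ = 2A(sin²θ − B)·sin 2θ, which is
    linear in the parameters (A, A·B); ordinary least squares in θ-space
    therefore solves the fit exactly.

    Returns
    -------
    (pmf_A, pmf_B) : tuple of float
        Curvature (kcal/mol) and center (λ units) of the PMF.
    """
    theta = np.asarray(theta_grid, dtype=float)
    force = np.asarray(mean_forces, dtype=float)
    if theta.shape != force.shape:
        raise ValueError("theta_grid and mean_forces must have the same length")
    if theta.size < 3:
        raise ValueError("need at least 3 TI grid points")
    if np.unique(theta).size < 2:
        raise SingularFitError("all theta grid points are identical")
    sin2t = np.sin(2.0 * theta)
    # design matrix columns multiply (A, A*B)
    X = np.column_stack([2.0 * np.sin(theta) ** 2 * sin2t, -2.0 * sin2t])
    if np.linalg.matrix_rank(X) < 2:
        raise SingularFitError("degenerate theta grid: design matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, force, rcond=None)
    a, ab = coef
    if a == 0.0:
        raise SingularFitError("fitted curvature is zero; center is undefined")
    return float(a), float(ab / a)


def _hill(ph, pka, n):
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


def fit_henderson_hasselbalch(
    curve: TitrationCurve, hill_n: float | None = None
) -> tuple[float, float]:
    """Fit the generalized Henderson–Hasselbalch curve to titration data.

    Parameters
    ----------
    curve
        Measured deprotonated fractions versus pH.
    hill_n
        If given, the Hill coefficient is held fixed at this value and only
        the pKa floats; otherwise both parameters are fitted.

    Returns
    -------
    (pKa, hill_n) : tuple of float
    """
    ph = curve.ph_values
    f = curve.deprotonated_fractions
    if ph.size < 3:
        raise ValueError("need at least 3 pH points spanning the transition")
    if float(f.max() - f.min()) < 1e-3:
        raise NoTransitionError(
            "titration curve is flat (all fractions ~0 or ~1): no transition to fit"
        )
    # initial pKa: pH closest to half-deprotonation
    p0_pka = float(ph[np.argmin(np.abs(f - 0.5))])
    if hill_n is not None:
        popt, _ = curve_fit(
            lambda x, pka: _hill(x, pka, hill_n), ph, f, p0=[p0_pka], maxfev=10000
        )
        return float(popt[0]), float(hill_n)
    popt, _ = curve_fit(
        _hill,
        ph,
        f,
        p0=[p0_pka, 1.0],
        bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def neutral_fraction(pKa, pH):
    """Equilibrium fraction of the neutral (deprotonated) species.

    Classic single-site Henderson–Hasselbalch: 1 / (1 + 10^{pKa − pH}).
    Vectorized over either argument.
    """
    pKa = np.asarray(pKa, dtype=float)
    pH = np.asarray(pH, dtype=float)
    if not (np.all(np.isfinite(pKa)) and np.all(np.isfinite(pH))):
        raise ValueError("pKa and pH must be finite")
    out = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return float(out) if out.ndim == 0 else out


def classify_state(lam: float, model: TitrationModel | None = None) -> str:
    """Classify a λ value as 'protonated', 'mixed' or 'deprotonated'.

    Thresholds come from ``model`` (default λ < 0.2 protonated, λ > 0.8
    deprotonated).
    """
    lo = model.lambda_lo if model is not None else 0.2
    hi = model.lambda_hi if model is not None else 0.8
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if lam < lo:
        return "protonated"
    if lam > hi:
        return "deprotonated"
    return "mixed"
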