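"""Assay post-processing: IAM-HPLC CHI calibration and BRET ratios.

Immobilized-artificial-membrane (IAM) chromatography reports drug
affinity for phospholipids through the chromatographic hydrophobicity
index (CHI).  The instrument is calibrated by regressing literature CHI
values of a standard calibrant mixture on their measured retention times;
the calibration is accepted only when the Pearson correlation exceeds
0.99, and column suitability requires every test compound to fall within
±5 CHI units of its literature value (inclusive).

BRET (bioluminescence resonance energy transfer) reports G-protein
activation as the acceptor/donor emission ratio (535 nm / 475 nm),
corrected by subtracting the vehicle ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PermweightError, SingularFitError

__all__ = [
    "CHICalibration",
    "BRETRecord",
    "calibrate_chi",
    "chi_from_tr",
    "suitability_check",
    "bret_ratio",
    "read_calibrant_table",
    "read_bret_trace",
]


@dataclass
class CHICalibration:
    """Linear CHI-vs-retention-time calibration."""

    slope: float  # CHI per minute
    intercept: float  # CHI
    pearson_r: float
    calibrant_table: pd.DataFrame
    r_threshold: float = 0.99
    suitability_tol: float = 5.0

    @property
    def valid(self) -> bool:
        return self.pearson_r > self.r_threshold


@dataclass
class BRETRecord:
    """One time point of a BRET trace."""

    time: float  # minutes
    em535: float
    em475: float
    corrected_ratio: float


def read_calibrant_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns name, tR (minutes) and CHI_literature."""
    df = pd.read_csv(path)
    missing = {"name", "tR", "CHI_literature"} - set(df.columns)
    if missing:
        raise PermweightError(f"calibrant table missing columns: {sorted(missing)}")
    return df


def calibrate_chi(
    calibrant_table: pd.DataFrame,
    r_threshold: float = 0.99,
    suitability_tol: float = 5.0,
) -> CHICalibration:
    """Ordinary least-squares line CHI = slope·tR + intercept.

    The calibration is flagged invalid (not rejected with an exception)
    when the Pearson r falls at or below ``r_threshold``.
    """
    if len(calibrant_table) < 3:
        raise PermweightError("need at least 3 calibrants")
    tr = calibrant_table["tR"].to_numpy(dtype=float)
    chi = calibrant_table["CHI_literature"].to_numpy(dtype=float)
    if np.unique(tr).size < 2:
        raise SingularFitError("all calibrant retention times are identical")
    fit = stats.linregress(tr, chi)
    return CHICalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        calibrant_table=calibrant_table.copy(),
        r_threshold=r_threshold,
        suitability_tol=suitability_tol,
    )


def chi_from_tr(calibration: CHICalibration, tR):
    """Convert retention time(s) to CHI using a valid calibration."""
    if not calibration.valid:
        raise PermweightError(
            f"calibration rejected: Pearson r = {calibration.pearson_r:.4f} "
            f"does not exceed the threshold {calibration.r_threshold}"
        )
    out = calibration.slope * np.asarray(tR, dtype=float) + calibration.intercept
    return float(out) if out.ndim == 0 else out


def suitability_check(
    measured, literature, tol: float = 5.0
) -> tuple[np.ndarray, bool]:
    """Per-compound |measured − literature| ≤ tol (inclusive) and overall pass.

    Returns (per-compound boolean array, overall pass = conjunction).
    """
    m = np.asarray(measured, dtype=float)
    lit = np.asarray(literature, dtype=float)
    if m.shape != lit.shape:
        raise PermweightError("measured and literature CHI lists differ in length")
    per = np.abs(m - lit) <= tol
    return per, bool(per.all())


def bret_ratio(em535, em475, vehicle_ratio: float = 0.0):
    """Vehicle-corrected BRET ratio: em535/em475 − vehicle_ratio."""
    em535 = np.asarray(em535, dtype=float)
    em475 = np.asarray(em475, dtype=float)
    if np.any(em475 <= 0):
        raise PermweightError("donor emission (475 nm) must be positive")
    out = em535 / em475 - vehicle_ratio
    return float(out) if out.ndim == 0 else out


def read_bret_trace(path: str | Path, vehicle_ratio: float = 0.0) -> list[BRETRecord]:
    """CSV with columns time, em535, em475 → corrected BRET records."""
    df = pd.read_csv(path)
    missing = {"time", "em535", "em475"} - set(df.columns)
    if missing:
        raise PermweightError(f"BRET trace missing columns: {sorted(missing)}")
    return [
        BRETRecord(
            time=float(r.time),
            em535=float(r.em535),
            em475=float(r.em475),
            corrected_ratio=bret_ratio(r.em535, r.em475, vehicle_ratio),
        )
        for r in df.itertuples()
    ]
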