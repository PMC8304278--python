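"""Calibration, detection limits and censored quantification (HRMS tier).

LOD and LOQ follow the intercept-deviation convention: LOD = 3.3·SD/b and
LOQ = 10·SD/b with SD the standard error of the intercept and b the slope of
the low-concentration calibration line.  Sample amounts are back-calculated
through the extraction (2 g homogenate brought to 40 mL, 1:10 dilution for
HRMS) and reported censored — ND, <LOD, <LOQ — below the respective limits,
as in regulatory result tables.

Long-chain polyphosphates have no commercial standards and cannot be
quantified individually; requesting quantification for them raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hrms_screen import DetectionRecord
from .species_db import PhosphateSpecies

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "lod",
    "loq",
    "quantify_species",
    "recovery",
    "precision",
]

# Default sample-preparation constants: 2 g into 40 mL, 1:10 dilution (HRMS).
SAMPLE_MASS_G = 2.0
EXTRACT_VOLUME_ML = 40.0
HRMS_DILUTION = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A least-squares calibration line for one species.

    Levels are µg/mL (nominal species mass for HRMS; µg/mL P₂O₅ for the
    conductivity channel).  ``sd_intercept`` is the OLS standard error of
    the intercept estimate.
    """

    species: str
    levels: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    sd_intercept: float
    r2: float

    def __post_init__(self):
        if len(self.levels) < 3:
            raise ValueError("calibration requires ≥ 3 levels")

    def concentration(self, response: float) -> float:
        """Invert the line: response → concentration (µg/mL)."""
        return (response - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[float], responses: Sequence[float], species: str = ""
) -> CalibrationCurve:
    """Fit an OLS line through a calibration series.

    ``sd_intercept`` uses the closed-form OLS expression
    s·√(1/n + x̄²/Sxx) with s² = SS_res/(n−2); an exact line gives 0.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and responses differ in length")
    if np.unique(x).size < 3:
        raise ValueError("need ≥ 3 distinct calibration levels")
    n = x.size
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    s2 = ss_res / (n - 2)
    sd_intercept = float(np.sqrt(s2 * (1.0 / n + xbar**2 / sxx)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CalibrationCurve(
        species=species,
        levels=tuple(float(v) for v in x),
        responses=tuple(float(v) for v in y),
        slope=slope,
        intercept=intercept,
        sd_intercept=sd_intercept,
        r2=r2,
    )


def lod(curve: CalibrationCurve) -> float:
    """Limit of detection: 3.3·SD/b (concentration units of the levels)."""
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return 3.3 * curve.sd_intercept / curve.slope


def loq(curve: CalibrationCurve) -> float:
    """Limit of quantification: 10·SD/b; always (10/3.3)·LOD."""
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return 10.0 * curve.sd_intercept / curve.slope


def quantify_species(
    record: DetectionRecord,
    curve: CalibrationCurve | None,
    species: PhosphateSpecies | None = None,
    sample_mass_g: float = SAMPLE_MASS_G,
    extract_volume_ml: float = EXTRACT_VOLUME_ML,
    dilution: float = HRMS_DILUTION,
    response: float | None = None,
) -> DetectionRecord:
    """Back-calculate a sample amount (µg/g) with censoring.

    The instrument response (default: the record's precursor peak area) is
    converted to extract concentration via the calibration line and scaled
    through dilution × volume / mass.  Results below the LOD on the sample
    scale report "<LOD", in [LOD, LOQ) report "<LOQ"; no signal is "ND".
    Unconfirmed records are never assigned a numeric amount.
    """
    if species is not None and not species.quantifiable:
        raise ValueError(
            f"{species.name}: no commercial standard; fingerprint-only species cannot be quantified"
        )
    if curve is None:
        raise ValueError("no calibration curve supplied")
    resp = record.precursor_area if response is None else response
    factor = dilution * extract_volume_ml / sample_mass_g  # µg/mL → µg/g
    if resp <= 0:
        record.amount = "ND"
        return record
    conc = curve.concentration(resp)
    amount = conc * factor
    lod_sample = lod(curve) * factor
    loq_sample = loq(curve) * factor
    if amount < lod_sample:
        record.amount = "<LOD"
    elif amount < loq_sample:
        record.amount = "<LOQ"
    elif not record.confirmed:
        # quantifiable signal without full confirmation stays censored
        record.amount = "<LOQ"
        record.notes.append("signal above LOQ but identification unconfirmed")
    else:
        record.amount = float(amount)
    return record


def recovery(spiked_before: float, spiked_after: float) -> float:
    """Extraction recovery, %: response spiked-before / spiked-after × 100."""
    if spiked_after == 0:
        raise ValueError("post-extraction spike response is zero")
    return 100.0 * spiked_before / spiked_after


def precision(replicates: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Intra- and inter-day coefficients of variation, %.

    ``replicates`` groups responses by day.  Intra-day CV is the mean of the
    within-day CVs (100·sd/mean, sd with n−1); inter-day CV is the CV of the
    day means.  With a single day the inter-day CV is 0.
    """
    groups = list(replicates.values()) if isinstance(replicates, Mapping) else list(replicates)
    if not groups:
        raise ValueError("no replicate groups supplied")
    cvs = []
    means = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("each day needs ≥ 2 replicates")
        m = arr.mean()
        if m == 0:
            raise ValueError("replicate mean is zero; CV undefined")
        cvs.append(100.0 * arr.std(ddof=1) / m)
        means.append(m)
    intra = float(np.mean(cvs))
    if len(means) < 2:
        return intra, 0.0
    mm = float(np.mean(means))
    if mm == 0:
        raise ValueError("grand mean is zero; CV undefined")
    inter = 100.0 * float(np.std(means, ddof=1)) / mm
    return intra, inter
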