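"""Assay-validation statistics: LOD, LOQ, CV and cross-method agreement.

LOD/LOQ follow the blank-standard-deviation convention (3.3*sigma/S and
10*sigma/S, with sigma the blank response SD and S the low-concentration
calibration slope).  Agreement between two half-maximal concentration sets
is ordinary least squares with the coefficient of determination.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from scipy import stats as _scipy_stats

from .errors import (
    DegenerateRegressionError,
    DesignError,
    InsufficientDataError,
    InvalidSlopeError,
    UndefinedCVError,
)

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class ValidationReport:
    analyte: str
    lod: float
    loq: float
    cv: float
    basis: str  # "absorbance" | "colour_value"


@dataclass(frozen=True)
class AgreementResult:
    pairs: Tuple[Tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def n(self) -> int:
        return len(self.pairs)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1) divided by the mean."""
    if len(values) < 2:
        raise InsufficientDataError(
            f"CV needs >= 2 replicate values, got {len(values)}"
        )
    mean = sum(values) / len(values)
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    return statistics.stdev(values) / mean


def lod_loq(sigma: float, slope: float) -> Tuple[float, float]:
    """(LOD, LOQ) = (3.3*sigma/slope, 10*sigma/slope)."""
    if sigma < 0:
        raise InsufficientDataError(f"sigma must be >= 0, got {sigma}")
    if slope <= 0:
        raise InvalidSlopeError(f"slope must be > 0, got {slope}")
    return LOD_FACTOR * sigma / slope, LOQ_FACTOR * sigma / slope


def response_noise_and_slope(
    points: Sequence[Tuple[float, float]],
    blanks: Sequence[float],
) -> Tuple[float, float]:
    """Estimate (sigma, slope) for LOD/LOQ from a low-concentration design.

    ``points`` are (concentration, mean response) pairs over the
    low-concentration linear segment; ``blanks`` are replicate blank
    responses.  sigma is the blank sample SD, slope the least-squares slope
    of mean response on concentration (pass its magnitude to
    :func:`lod_loq` for decreasing responses).
    """
    if len(blanks) < 2:
        raise InsufficientDataError(
            f"need >= 2 blank replicates, got {len(blanks)}"
        )
    concs = [c for c, _ in points]
    if len(set(concs)) < 3:
        raise DesignError(
            f"need >= 3 distinct concentration levels, got {len(set(concs))}"
        )
    if max(concs) == min(concs):
        raise DesignError("zero variance in concentrations")
    sigma = statistics.stdev(blanks)
    responses = [r for _, r in points]
    fit = _scipy_stats.linregress(concs, responses)
    return sigma, float(fit.slope)


def per_level_cvs(
    records: Sequence, response_attr: str
) -> List[Tuple[float, float]]:
    """Per-concentration CV over replicates; levels with n < 2 are skipped.

    Returns (concentration, cv) pairs sorted by concentration, computed on
    raw responses of ``role="reaction"`` records.
    """
    by_conc = {}
    for r in records:
        if getattr(r, "role", "reaction") != "reaction":
            continue
        by_conc.setdefault(r.concentration, []).append(
            float(getattr(r, response_attr))
        )
    out = []
    for conc in sorted(by_conc):
        vals = by_conc[conc]
        if len(vals) >= 2:
            out.append((conc, cv(vals)))
    return out


def mean_cv(records: Sequence, response_attr: str) -> float:
    """Mean of per-level CVs across all concentration levels with replicates."""
    levels = per_level_cvs(records, response_attr)
    if not levels:
        raise InsufficientDataError("no concentration level has >= 2 replicates")
    return sum(v for _, v in levels) / len(levels)


def method_agreement(pairs: Sequence[Tuple[float, float]]) -> AgreementResult:
    """OLS of the second member on the first, with R^2 = 1 - SSres/SStot."""
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    xs = [float(a) for a, _ in pairs]
    ys = [float(b) for _, b in pairs]
    if not all(map(_is_finite, xs + ys)):
        raise InsufficientDataError("pairs must be finite")
    if max(xs) == min(xs):
        raise DegenerateRegressionError("zero variance in the first method's values")
    fit = _scipy_stats.linregress(xs, ys)
    slope, intercept = float(fit.slope), float(fit.intercept)
    y_mean = sum(ys) / len(ys)
    ss_res = sum((y - (slope * x + intercept)) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - y_mean) ** 2 for y in ys)
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # guard tiny negative round-off
    r_squared = min(1.0, max(0.0, r_squared))
    return AgreementResult(
        pairs=tuple((x, y) for x, y in zip(xs, ys)),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
    )


def _is_finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))
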