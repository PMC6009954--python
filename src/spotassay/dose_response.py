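"""Dose-response curve assembly and half-maximal estimators.

Two branches share the machinery:

* absorbance branch — SC50, the concentration halving the initial (blank)
  absorbance of the radical solution;
* colour branch — CSC50, the concentration raising the spot colour value
  (mean grey value) halfway from the zero-scavenging blank towards the
  complete-reduction maximum, estimated either by direct half-maximum
  interpolation or from the first-derivative curve (the concentration of the
  steepest response change).

Interpolation happens on the linear concentration axis, mirroring graphical
read-off from raw concentration plots; no parametric (Hill/4PL) fitting.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    DegenerateRangeError,
    InsufficientDataError,
    InvalidControlError,
    MissingBlankError,
    UnitError,
)
from .plate_model import (
    CurvePoint,
    DoseResponseCurve,
    HalfMaxResult,
)


@dataclass(frozen=True)
class DerivativeCurve:
    """Forward finite differences of a response curve at pair midpoints."""

    sample_id: str
    points: Tuple[Tuple[float, float], ...]  # (midpoint concentration, slope)

    def __post_init__(self) -> None:
        mids = [m for m, _ in self.points]
        if not all(b > a for a, b in zip(mids, mids[1:])):
            raise InsufficientDataError("midpoints must be strictly increasing")


_RESPONSE_ATTR = {"colour_value": "colour_value", "absorbance": "absorbance"}


def aggregate_curve(records: Sequence, response_kind: str) -> DoseResponseCurve:
    """Collapse replicate records into a per-concentration mean curve.

    Records need ``sample_id``, ``concentration``, ``role``, ``unit`` and the
    response attribute named by ``response_kind`` (``colour_value`` or
    ``absorbance``).  Only ``role="reaction"`` records form the curve; the
    mean of ``role="reagent_blank"`` records (the unscavenged mixture)
    becomes ``blank_response`` when present.  SD is the sample standard
    deviation (n-1 denominator), zero for single replicates.
    """
    if response_kind not in _RESPONSE_ATTR:
        raise InsufficientDataError(f"unknown response_kind {response_kind!r}")
    attr = _RESPONSE_ATTR[response_kind]

    reactions = [r for r in records if r.role == "reaction"]
    units = {r.unit for r in records}
    if len(units) > 1:
        raise UnitError(f"mixed concentration units in one curve: {sorted(units)}")
    by_conc: Dict[float, List[float]] = {}
    for r in reactions:
        by_conc.setdefault(r.concentration, []).append(float(getattr(r, attr)))
    if len(by_conc) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct concentrations, got {len(by_conc)}"
        )

    points = []
    for conc in sorted(by_conc):
        vals = by_conc[conc]
        mean = sum(vals) / len(vals)
        sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
        points.append(CurvePoint(conc, mean, sd, len(vals)))

    blanks = [float(getattr(r, attr)) for r in records if r.role == "reagent_blank"]
    blank = sum(blanks) / len(blanks) if blanks else None

    sample_ids = {r.sample_id for r in reactions}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else "|".join(sorted(sample_ids))
    return DoseResponseCurve(
        sample_id=sample_id,
        response_kind=response_kind,
        points=tuple(points),
        blank_response=blank,
        unit=units.pop() if units else "uM",
    )


def blank_correct_extract(
    curve: DoseResponseCurve,
    extract_blanks: Union[float, Mapping[float, float]],
    plate_baseline: float,
) -> DoseResponseCurve:
    """Subtract the extract's self-colour from a colour-value curve.

    Coloured extracts lighten/darken their drops independently of the
    radical reaction; the extract-blank drops (sample + solvent only) give
    that self-colour per concentration.  The additive correction is

        corrected = response - (extract_blank - plate_baseline)

    where ``plate_baseline`` is the clean-plate grey level.  Pass a single
    float for a pooled blank or a mapping concentration -> blank response.
    """
    def correction_for(conc: float) -> float:
        if isinstance(extract_blanks, Mapping):
            if conc not in extract_blanks:
                raise MissingBlankError(
                    f"no extract blank for concentration {conc}"
                )
            return extract_blanks[conc] - plate_baseline
        return float(extract_blanks) - plate_baseline

    points = tuple(
        replace(p, mean=p.mean - correction_for(p.concentration))
        for p in curve.points
    )
    return replace(
        curve,
        points=points,
        notes=curve.notes + ("extract_blank_corrected",),
    )


def percent_scavenging(a_control: float, a_sample: float) -> float:
    """Percent radical scavenged: ``100 * (a_control - a_sample) / a_control``."""
    if a_control <= 0:
        raise InvalidControlError(f"control absorbance must be > 0, got {a_control}")
    return 100.0 * (a_control - a_sample) / a_control


def _is_monotone(values: Sequence[float], decreasing: bool) -> bool:
    if decreasing:
        return all(b <= a for a, b in zip(values, values[1:]))
    return all(b >= a for a, b in zip(values, values[1:]))


def _first_crossing(
    concs: Sequence[float],
    means: Sequence[float],
    target: float,
    increasing: bool,
) -> Tuple[Optional[float], Optional[Tuple[Tuple[float, float], Tuple[float, float]]], str]:
    """Locate the first crossing of ``target`` walking from low concentration.

    Returns (value, bracketing points, status).  Linear interpolation on the
    linear concentration axis.  Censoring: the curve never reaching the
    target on its way up (colour) / down (absorbance) is ``censored_high``
    (a higher concentration would be needed); the lowest concentration
    already past the target is ``censored_low``.
    """
    status = "ok"
    if not _is_monotone(means, decreasing=not increasing):
        status = "non_monotone_warning"

    for i, (c, m) in enumerate(zip(concs, means)):
        if m == target:
            pt = (c, m)
            return c, (pt, pt), status

    for i in range(len(concs) - 1):
        lo, hi = means[i], means[i + 1]
        if (lo - target) * (hi - target) < 0:
            frac = (target - lo) / (hi - lo)
            value = concs[i] + frac * (concs[i + 1] - concs[i])
            bracket = ((concs[i], lo), (concs[i + 1], hi))
            return value, bracket, status

    # no crossing anywhere
    first = means[0]
    past_at_start = first > target if increasing else first < target
    return None, None, "censored_low" if past_at_start else "censored_high"


def sc50_from_absorbance(curve: DoseResponseCurve) -> HalfMaxResult:
    """SC50: concentration halving the initial absorbance.

    The initial absorbance A0 is the curve's ``blank_response`` (reagent
    blank / unscavenged control); the target is A0/2 on the decreasing mean
    curve, located by the first crossing from low concentration.
    """
    if curve.response_kind != "absorbance":
        raise InsufficientDataError("sc50_from_absorbance needs an absorbance curve")
    if curve.blank_response is None:
        raise MissingBlankError("initial absorbance (blank_response) is required")
    target = curve.blank_response / 2.0
    value, bracket, status = _first_crossing(
        curve.concentrations, curve.means, target, increasing=False
    )
    return HalfMaxResult(
        sample_id=curve.sample_id,
        method="sc50_absorbance",
        value=value,
        unit=curve.unit,
        bracketing_points=bracket,
        status=status,
    )


def csc50_halfmax(curve: DoseResponseCurve) -> HalfMaxResult:
    """CSC50 by direct half-maximum read-off on the colour-value curve.

    Target = blank + (max - blank)/2, where blank is the zero-scavenging
    colour and max the complete-reduction colour.  Missing references
    default to the observed extremes of the mean curve and are flagged in
    diagnostics (a defaulted max biases the estimate low when the plateau
    was not reached).
    """
    if curve.response_kind != "colour_value":
        raise InsufficientDataError("csc50_halfmax needs a colour-value curve")
    diagnostics: List[str] = []
    blank = curve.blank_response
    if blank is None:
        blank = min(curve.means)
        diagnostics.append("blank_defaulted_to_min_observed")
    max_r = curve.max_response
    if max_r is None:
        max_r = max(curve.means)
        diagnostics.append("max_defaulted_to_max_observed")
    if max_r <= blank:
        raise DegenerateRangeError(
            f"max response {max_r} not above blank {blank}"
        )
    target = blank + (max_r - blank) / 2.0
    value, bracket, status = _first_crossing(
        curve.concentrations, curve.means, target, increasing=True
    )
    return HalfMaxResult(
        sample_id=curve.sample_id,
        method="csc50_halfmax",
        value=value,
        unit=curve.unit,
        bracketing_points=bracket,
        status=status,
        diagnostics=tuple(diagnostics),
    )


def derivative_curve(curve: DoseResponseCurve) -> DerivativeCurve:
    """First-derivative curve: forward differences of consecutive means.

    Each difference quotient is plotted at the arithmetic midpoint of its
    concentration pair; no smoothing is applied.
    """
    if len(curve.points) < 3:
        raise InsufficientDataError(
            f"derivative curve needs >= 3 points, got {len(curve.points)}"
        )
    concs = curve.concentrations
    means = curve.means
    points = tuple(
        (
            (concs[i] + concs[i + 1]) / 2.0,
            (means[i + 1] - means[i]) / (concs[i + 1] - concs[i]),
        )
        for i in range(len(concs) - 1)
    )
    return DerivativeCurve(sample_id=curve.sample_id, points=points)


def csc50_derivative(curve: DoseResponseCurve) -> HalfMaxResult:
    """CSC50 from the derivative graph: the concentration of the steepest rise.

    Returns the midpoint concentration of the maximum difference quotient;
    ties go to the lowest concentration and are flagged in diagnostics.
    """
    if curve.response_kind != "colour_value":
        raise InsufficientDataError("csc50_derivative needs a colour-value curve")
    deriv = derivative_curve(curve)
    slopes = [s for _, s in deriv.points]
    best = max(slopes)
    idx = slopes.index(best)  # first (lowest-concentration) maximum
    diagnostics: Tuple[str, ...] = ()
    if slopes.count(best) > 1:
        diagnostics = ("tie_broken_to_lowest_concentration",)
    concs = curve.concentrations
    means = curve.means
    bracket = ((concs[idx], means[idx]), (concs[idx + 1], means[idx + 1]))
    return HalfMaxResult(
        sample_id=curve.sample_id,
        method="csc50_derivative",
        value=deriv.points[idx][0],
        unit=curve.unit,
        bracketing_points=bracket,
        status="ok",
        diagnostics=diagnostics,
    )
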