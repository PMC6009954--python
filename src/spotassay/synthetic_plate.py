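"""Ground-truth simulator for the assay pipeline.

Simulates scavenging chemistry with a logistic stand-in (guaranteeing
f(c50) = 0.5), renders plate images with known per-spot grey values, and
generates absorbance ladders, so every downstream stage can be tested
against known truth without laboratory data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dose_response import aggregate_curve, csc50_derivative, csc50_halfmax, sc50_from_absorbance
from .errors import InsufficientDataError, InvalidParameterError, LayoutError
from .image_quant import PlateImage, quantify_plate
from .plate_model import (
    AbsorbanceRecord,
    DilutionSeries,
    PlateLayout,
    layout_to_wells,
)
from .validation_metrics import AgreementResult, method_agreement

FORMS = ("logistic_linear", "logistic_log")


@dataclass(frozen=True)
class ScavengingModel:
    """Fraction of radical scavenged as a function of concentration.

    ``logistic_log`` is a Hill-type curve, f(c) = 1 / (1 + (c50/c)**hill),
    exactly 0 at c=0 and 0.5 at c50.  ``logistic_linear`` is a logistic in
    raw concentration, f(c) = 1 / (1 + exp(-hill*(c/c50 - 1))), symmetric
    about c50 on the linear axis (choose hill >= ~5 to keep f(0) small).
    """

    true_c50: float
    hill: float = 2.0
    form: str = "logistic_log"

    def __post_init__(self) -> None:
        if self.true_c50 <= 0:
            raise InvalidParameterError("true_c50 must be > 0")
        if self.hill <= 0:
            raise InvalidParameterError("hill must be > 0")
        if self.form not in FORMS:
            raise InvalidParameterError(f"unknown form {self.form!r}")


def fraction_scavenged(model: ScavengingModel, c: float) -> float:
    """Scavenged fraction in [0, 1]; strictly increasing, f(c50) = 0.5."""
    if c < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {c}")
    if model.form == "logistic_log":
        if c == 0:
            return 0.0
        return 1.0 / (1.0 + (model.true_c50 / c) ** model.hill)
    return 1.0 / (1.0 + math.exp(-model.hill * (c / model.true_c50 - 1.0)))


def simulate_absorbance_series(
    model: ScavengingModel,
    series: DilutionSeries,
    a0: float = 1.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sample",
) -> List[AbsorbanceRecord]:
    """Spectrophotometric branch: A(c) = a0*(1 - f(c)) + noise, floored at 0.

    Also emits ``n_replicates`` reagent-blank records at A ~ a0 (the
    unscavenged control).  Reproducible per seed.
    """
    if a0 <= 0:
        raise InvalidParameterError(f"a0 must be > 0, got {a0}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records: List[AbsorbanceRecord] = []
    for c in series.concentrations():
        clean = a0 * (1.0 - fraction_scavenged(model, c))
        for rep in range(n_replicates):
            a = max(0.0, clean + float(rng.normal(0.0, noise_sd)) if noise_sd else clean)
            records.append(
                AbsorbanceRecord(
                    sample_id=sample_id,
                    concentration=c,
                    replicate=rep,
                    role="reaction",
                    absorbance=a,
                    unit=series.unit,
                )
            )
    for rep in range(n_replicates):
        a = max(0.0, a0 + float(rng.normal(0.0, noise_sd)) if noise_sd else a0)
        records.append(
            AbsorbanceRecord(
                sample_id=sample_id,
                concentration=0.0,
                replicate=rep,
                role="reagent_blank",
                absorbance=a,
                unit=series.unit,
            )
        )
    return records


@dataclass
class RenderConfig:
    """Parameters of the plate render and the scanner acquisition transform.

    A spot's clean interior grey is ``background_grey - depth`` where the
    darkening depth depends on the well role: ``dpph_dark_depth * (1 - f(c))``
    for reaction wells, ``dpph_dark_depth`` for reagent blanks (no
    scavenging), and ``extract_self_depth`` for extract blanks (sample +
    solvent only, no radical).  The scanner transform is
    ``g' = scan_contrast*(g - 128) + 128 + scan_brightness`` followed by
    clipping to [0, 255]; by default it is applied before noise
    (scanner-referred signal, sensor-dominated noise).
    """

    layout: PlateLayout
    background_grey: float = 230.0
    dpph_dark_depth: float = 150.0
    noise_sd: float = 0.0
    edge_softness: float = 2.0
    scan_brightness: float = 0.0
    scan_contrast: float = 1.0
    seed: int = 0
    extract_self_depth: float = 0.0
    noise_before_scan: bool = False
    core_pad: float = 1.5  # flat interior extends this far beyond the ROI radius

    def __post_init__(self) -> None:
        if not 0 <= self.background_grey <= 255:
            raise InvalidParameterError("background_grey must be in [0, 255]")
        if self.noise_sd < 0 or self.edge_softness < 0:
            raise InvalidParameterError("noise_sd and edge_softness must be >= 0")
        if self.scan_contrast <= 0:
            raise InvalidParameterError("scan_contrast must be > 0")


def scan_transform(values: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """Affine brightness/contrast transform with clipping to [0, 255]."""
    return np.clip(gain * (np.asarray(values, dtype=np.float64) - 128.0) + 128.0 + offset, 0.0, 255.0)


@dataclass(frozen=True)
class GroundTruthSpot:
    """Intended interior grey of one spot, post scan transform, pre noise."""

    row: int
    col: int
    sample_id: str
    concentration: float
    replicate: int
    role: str
    unit: str
    true_mean_grey: float


def _spot_depth(config: RenderConfig, model: ScavengingModel, role: str, c: float) -> float:
    if role == "reaction":
        return config.dpph_dark_depth * (1.0 - fraction_scavenged(model, c)) + config.extract_self_depth
    if role == "reagent_blank":
        return config.dpph_dark_depth
    if role == "extract_blank":
        return config.extract_self_depth
    return 0.0  # solvent_control: clean solvent, no darkening


def render_plate(
    model: ScavengingModel,
    config: RenderConfig,
    series: Optional[DilutionSeries] = None,
    n_replicates: int = 3,
    sample_id: str = "sample",
    n_reagent_blanks: int = 3,
) -> Tuple[PlateImage, List[GroundTruthSpot]]:
    """Render a plate image plus its ground-truth table.

    If the layout in ``config`` has no wells, a ladder from ``series`` is
    placed row-major with ``n_reagent_blanks`` reagent blanks appended.
    Spots are soft-edged discs (raised-cosine edge of ``edge_softness``
    pixels) whose flat core extends ``core_pad`` pixels beyond the ROI
    radius, so the measured ROI sees only interior pixels.  Deterministic
    per seed.
    """
    layout = config.layout
    if not layout.wells:
        if series is None:
            raise LayoutError("layout has no wells and no dilution series was given")
        layout = layout_to_wells(
            layout, series, sample_id, n_replicates, n_reagent_blanks=n_reagent_blanks
        )

    height = int(math.ceil(2 * layout.origin[1] + (layout.n_rows - 1) * layout.pitch_y)) + 1
    width = int(math.ceil(2 * layout.origin[0] + (layout.n_cols - 1) * layout.pitch_x)) + 1
    canvas = np.full((height, width), float(config.background_grey))

    core = layout.spot_radius + config.core_pad
    outer = core + config.edge_softness
    truth: List[GroundTruthSpot] = []
    for well in layout.wells:
        cx, cy = layout.centre(well.row, well.col)
        depth = _spot_depth(config, model, well.role, well.concentration)
        spot_grey = config.background_grey - depth
        x0 = max(0, int(math.floor(cx - outer)))
        x1 = min(width - 1, int(math.ceil(cx + outer)))
        y0 = max(0, int(math.floor(cy - outer)))
        y1 = min(height - 1, int(math.ceil(cy + outer)))
        ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        d = np.hypot(xs - cx, ys - cy)
        if config.edge_softness > 0:
            w = np.where(
                d <= core,
                1.0,
                np.where(
                    d >= outer,
                    0.0,
                    0.5 * (1.0 + np.cos(math.pi * (d - core) / config.edge_softness)),
                ),
            )
        else:
            w = (d <= core).astype(np.float64)
        patch = canvas[y0 : y1 + 1, x0 : x1 + 1]
        canvas[y0 : y1 + 1, x0 : x1 + 1] = patch + w * (spot_grey - patch)
        truth.append(
            GroundTruthSpot(
                row=well.row,
                col=well.col,
                sample_id=well.sample_id,
                concentration=well.concentration,
                replicate=well.replicate,
                role=well.role,
                unit=well.unit,
                true_mean_grey=float(
                    scan_transform(
                        np.array([spot_grey]), config.scan_contrast, config.scan_brightness
                    )[0]
                ),
            )
        )

    rng = np.random.default_rng(config.seed)
    if config.noise_before_scan:
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
        canvas = scan_transform(canvas, config.scan_contrast, config.scan_brightness)
    else:
        canvas = scan_transform(canvas, config.scan_contrast, config.scan_brightness)
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)

    pixels = np.floor(np.clip(canvas, 0.0, 255.0) + 0.5).astype(np.uint8)
    return PlateImage(pixels=pixels, source_path="<synthetic>"), truth


@dataclass(frozen=True)
class AnalyteRecovery:
    sample_id: str
    true_c50: float
    sc50: Optional[float]
    sc50_status: str
    csc50_halfmax: Optional[float]
    csc50_halfmax_status: str
    csc50_derivative: Optional[float]
    csc50_derivative_status: str

    @property
    def halfmax_bias(self) -> Optional[float]:
        if self.csc50_halfmax is None:
            return None
        return self.csc50_halfmax - self.true_c50


@dataclass(frozen=True)
class RecoveryReport:
    analytes: Tuple[AnalyteRecovery, ...]
    agreement_halfmax: Optional[AgreementResult]
    agreement_derivative: Optional[AgreementResult]


def _default_layout() -> PlateLayout:
    return PlateLayout(
        n_rows=3, n_cols=10, origin=(24.0, 24.0), pitch_x=36.0, pitch_y=36.0, spot_radius=10.0
    )


def end_to_end_recovery(
    true_c50s: Sequence[float],
    noise_sd_image: float = 0.0,
    noise_sd_absorbance: float = 0.0,
    seed: int = 0,
    ladder_top_factor: float = 12.0,
    dilution_factor: float = 2.0,
    n_levels: int = 9,
    n_replicates: int = 3,
    a0: float = 1.0,
    hill: float = 2.0,
    form: str = "logistic_log",
    unit: str = "uM",
    layout: Optional[PlateLayout] = None,
) -> RecoveryReport:
    """Run both branches on k synthetic analytes and compare the estimates.

    For each analyte a two-fold ladder with top ``ladder_top_factor *
    true_c50`` is simulated through the absorbance branch (-> SC50) and
    rendered/quantified through the image branch (-> CSC50 by half-max and
    derivative), then the paired estimates are regressed against each other.
    """
    if len(true_c50s) < 3:
        raise InsufficientDataError(f"need >= 3 analytes, got {len(true_c50s)}")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * len(true_c50s))

    analytes: List[AnalyteRecovery] = []
    pairs_halfmax: List[Tuple[float, float]] = []
    pairs_deriv: List[Tuple[float, float]] = []
    for i, c50 in enumerate(true_c50s):
        sample_id = f"analyte_{i}"
        model = ScavengingModel(true_c50=c50, hill=hill, form=form)
        series = DilutionSeries(
            top_concentration=ladder_top_factor * c50,
            dilution_factor=dilution_factor,
            n_levels=n_levels,
            unit=unit,
        )

        abs_records = simulate_absorbance_series(
            model,
            series,
            a0=a0,
            noise_sd=noise_sd_absorbance,
            n_replicates=n_replicates,
            seed=int(sub_seeds[2 * i]),
            sample_id=sample_id,
        )
        abs_curve = aggregate_curve(abs_records, "absorbance")
        sc50 = sc50_from_absorbance(abs_curve)

        config = RenderConfig(
            layout=layout if layout is not None else _default_layout(),
            noise_sd=noise_sd_image,
            seed=int(sub_seeds[2 * i + 1]),
        )
        image, _ = render_plate(
            model, config, series, n_replicates=n_replicates, sample_id=sample_id
        )
        rendered_layout = config.layout
        if not rendered_layout.wells:
            rendered_layout = layout_to_wells(
                rendered_layout, series, sample_id, n_replicates, n_reagent_blanks=3
            )
        spots = quantify_plate(image, rendered_layout, refine=True)
        colour_curve = aggregate_curve(spots, "colour_value")
        halfmax = csc50_halfmax(colour_curve)
        deriv = csc50_derivative(colour_curve)

        analytes.append(
            AnalyteRecovery(
                sample_id=sample_id,
                true_c50=c50,
                sc50=sc50.value,
                sc50_status=sc50.status,
                csc50_halfmax=halfmax.value,
                csc50_halfmax_status=halfmax.status,
                csc50_derivative=deriv.value,
                csc50_derivative_status=deriv.status,
            )
        )
        if sc50.value is not None and halfmax.value is not None:
            pairs_halfmax.append((sc50.value, halfmax.value))
        if sc50.value is not None and deriv.value is not None:
            pairs_deriv.append((sc50.value, deriv.value))

    agreement_halfmax = (
        method_agreement(pairs_halfmax) if len(pairs_halfmax) >= 3 else None
    )
    agreement_derivative = (
        method_agreement(pairs_deriv) if len(pairs_deriv) >= 3 else None
    )
    return RecoveryReport(
        analytes=tuple(analytes),
        agreement_halfmax=agreement_halfmax,
        agreement_derivative=agreement_derivative,
    )
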