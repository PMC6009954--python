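"""Domain types shared by all pipeline stages.

Plate geometry, serial-dilution ladders, spot measurements, dose-response
curves and half-maximum results.  Concentration units are carried as opaque
labels; mixing units within one curve is an error caught downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

from .errors import InvalidParameterError, LayoutError

ROLES = frozenset({"reaction", "reagent_blank", "extract_blank", "solvent_control"})

#: increments when the layout file schema changes incompatibly
LAYOUT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class WellAssignment:
    """One occupied grid cell: what was dropped there and why."""

    row: int
    col: int
    sample_id: str
    concentration: float
    replicate: int
    role: str = "reaction"
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidParameterError(
                f"concentration must be >= 0, got {self.concentration}"
            )
        if self.role not in ROLES:
            raise InvalidParameterError(
                f"unknown role {self.role!r}; expected one of {sorted(ROLES)}"
            )
        if self.row < 0 or self.col < 0:
            raise InvalidParameterError("row/col indices must be >= 0")
        if self.replicate < 0:
            raise InvalidParameterError("replicate index must be >= 0")


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution ladder: level k has concentration top / factor**k."""

    top_concentration: float
    dilution_factor: float
    n_levels: int
    unit: str = "uM"

    def __post_init__(self) -> None:
        # delegate validation to the builder so both paths share one contract
        build_serial_dilution(
            self.top_concentration, self.dilution_factor, self.n_levels
        )

    def concentrations(self) -> list:
        return build_serial_dilution(
            self.top_concentration, self.dilution_factor, self.n_levels
        )


def build_serial_dilution(top: float, factor: float, n_levels: int) -> list:
    """Return the strictly decreasing ladder ``[top/factor**k for k in 0..n-1]``.

    A "1:1" serial dilution corresponds to ``factor=2`` (each level is half
    the previous one).
    """
    if not top > 0:
        raise InvalidParameterError(f"top concentration must be > 0, got {top}")
    if not factor > 1:
        raise InvalidParameterError(f"dilution factor must be > 1, got {factor}")
    if n_levels < 2:
        raise InvalidParameterError(f"need at least 2 levels, got {n_levels}")
    return [top / factor**k for k in range(n_levels)]


@dataclass
class PlateLayout:
    """Geometry of the spot grid plus the well assignments placed on it.

    ``origin`` is the pixel coordinate (x, y) of the spot centre at grid
    position (row 0, col 0); ``pitch_x``/``pitch_y`` are the centre-to-centre
    spacings along columns and rows respectively.
    """

    n_rows: int
    n_cols: int
    origin: Tuple[float, float] = (30.0, 30.0)
    pitch_x: float = 40.0
    pitch_y: float = 40.0
    spot_radius: float = 12.0
    wells: Tuple[WellAssignment, ...] = ()

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError("grid must have at least 1 row and 1 column")
        if self.spot_radius < 1:
            raise LayoutError("spot radius must be >= 1 pixel")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise LayoutError("pitches must be positive")
        if 2 * self.spot_radius >= min(self.pitch_x, self.pitch_y):
            raise LayoutError(
                "ROIs overlap: 2*spot_radius must be < min(pitch_x, pitch_y)"
            )
        self.wells = tuple(self.wells)
        seen = set()
        for w in self.wells:
            if w.row >= self.n_rows or w.col >= self.n_cols:
                raise LayoutError(f"well ({w.row}, {w.col}) outside the grid")
            if (w.row, w.col) in seen:
                raise LayoutError(f"duplicate well assignment at ({w.row}, {w.col})")
            seen.add((w.row, w.col))

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    def centre(self, row: int, col: int) -> Tuple[float, float]:
        """Nominal pixel centre (x, y) of the given grid cell."""
        return (
            self.origin[0] + col * self.pitch_x,
            self.origin[1] + row * self.pitch_y,
        )

    # -- layout file format (JSON, versioned) ------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": LAYOUT_FORMAT_VERSION,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin": list(self.origin),
            "pitch_x": self.pitch_x,
            "pitch_y": self.pitch_y,
            "spot_radius": self.spot_radius,
            "wells": [
                {
                    "row": w.row,
                    "col": w.col,
                    "sample_id": w.sample_id,
                    "concentration": w.concentration,
                    "replicate": w.replicate,
                    "role": w.role,
                    "unit": w.unit,
                }
                for w in self.wells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        version = d.get("format_version")
        if version != LAYOUT_FORMAT_VERSION:
            raise LayoutError(
                f"unsupported layout format_version {version!r}; "
                f"expected {LAYOUT_FORMAT_VERSION}"
            )
        wells = tuple(WellAssignment(**w) for w in d.get("wells", []))
        return cls(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            origin=tuple(d["origin"]),
            pitch_x=d["pitch_x"],
            pitch_y=d["pitch_y"],
            spot_radius=d["spot_radius"],
            wells=wells,
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PlateLayout":
        return cls.from_dict(json.loads(Path(path).read_text()))


def layout_to_wells(
    layout: PlateLayout,
    series: DilutionSeries,
    sample_id: str,
    n_replicates: int,
    fill_order: str = "row-major",
    n_reagent_blanks: int = 0,
    extract_blanks: bool = False,
) -> PlateLayout:
    """Place a dilution ladder (plus optional blanks) onto an empty grid.

    Assignments are laid down in ``fill_order`` ("row-major" or
    "column-major") with replicates adjacent: cell k receives dilution level
    ``k // n_replicates``, replicate ``k % n_replicates``.  Reaction wells
    come first, then ``n_reagent_blanks`` reagent-blank wells (concentration
    0) and, if requested, one extract-blank well per dilution level.
    """
    if layout.wells:
        raise LayoutError("layout already has wells assigned")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if fill_order not in ("row-major", "column-major"):
        raise InvalidParameterError(f"unknown fill_order {fill_order!r}")

    concs = series.concentrations()
    assignments = []
    for level, c in enumerate(concs):
        for rep in range(n_replicates):
            assignments.append((sample_id, c, rep, "reaction"))
    for rep in range(n_reagent_blanks):
        assignments.append((sample_id, 0.0, rep, "reagent_blank"))
    if extract_blanks:
        for c in concs:
            assignments.append((sample_id, c, 0, "extract_blank"))

    if len(assignments) > layout.capacity:
        raise LayoutError(
            f"layout capacity {layout.capacity} exceeded: "
            f"{len(assignments)} assignments requested"
        )

    if fill_order == "row-major":
        cells = [
            (r, c) for r in range(layout.n_rows) for c in range(layout.n_cols)
        ]
    else:
        cells = [
            (r, c) for c in range(layout.n_cols) for r in range(layout.n_rows)
        ]

    wells = tuple(
        WellAssignment(
            row=cell[0],
            col=cell[1],
            sample_id=sid,
            concentration=conc,
            replicate=rep,
            role=role,
            unit=series.unit,
        )
        for cell, (sid, conc, rep, role) in zip(cells, assignments)
    )
    return replace(layout, wells=wells)


@dataclass(frozen=True)
class SpotMeasurement:
    """One spot's mean grey value with its ROI and provenance."""

    sample_id: str
    concentration: float
    replicate: int
    role: str
    centre: Tuple[float, float]
    radius: float
    colour_value: float
    n_pixels: int
    unit: str = "uM"
    row: Optional[int] = None
    col: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.colour_value <= 255:
            raise InvalidParameterError(
                f"colour value {self.colour_value} outside [0, 255]"
            )
        if self.n_pixels < 1:
            raise InvalidParameterError("n_pixels must be >= 1")
        if self.role not in ROLES:
            raise InvalidParameterError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometric reading (517 nm branch)."""

    sample_id: str
    concentration: float
    replicate: int
    role: str
    absorbance: float
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise InvalidParameterError("absorbance must be >= 0")
        if self.role not in ROLES:
            raise InvalidParameterError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class CurvePoint:
    concentration: float
    mean: float
    sd: float
    n_replicates: int


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-sample series of (concentration, mean response) over replicates.

    ``blank_response`` is the zero-scavenging reference (reagent blank:
    unreacted mixture).  ``max_response`` is the response at complete
    reduction — an observed plateau or a supplied value; ``None`` means
    "default to the largest observed mean" (flagged by the estimators).
    """

    sample_id: str
    response_kind: str  # "colour_value" | "absorbance"
    points: Tuple[CurvePoint, ...]
    blank_response: Optional[float] = None
    max_response: Optional[float] = None
    unit: str = "uM"
    notes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.response_kind not in ("colour_value", "absorbance"):
            raise InvalidParameterError(
                f"unknown response_kind {self.response_kind!r}"
            )
        concs = [p.concentration for p in self.points]
        if any(c < 0 for c in concs):
            raise InvalidParameterError("concentrations must be >= 0")
        if not all(b > a for a, b in zip(concs, concs[1:])):
            raise InvalidParameterError("concentrations must be strictly increasing")
        for p in self.points:
            if p.n_replicates < 1:
                raise InvalidParameterError("n_replicates must be >= 1")
            if p.sd < 0:
                raise InvalidParameterError("sd must be >= 0")

    @property
    def concentrations(self) -> list:
        return [p.concentration for p in self.points]

    @property
    def means(self) -> list:
        return [p.mean for p in self.points]


#: result status vocabulary for half-maximum estimates
STATUSES = ("ok", "censored_low", "censored_high", "non_monotone_warning")

METHODS = ("sc50_absorbance", "csc50_halfmax", "csc50_derivative")


@dataclass(frozen=True)
class HalfMaxResult:
    """A half-maximal concentration estimate with its diagnostics.

    ``bracketing_points`` holds the two (concentration, mean) curve points
    used for interpolation — for the derivative method, the pair whose
    midpoint won.  ``value`` is ``None`` when the estimate is censored.
    """

    sample_id: str
    method: str
    value: Optional[float]
    unit: str
    bracketing_points: Optional[Tuple[Tuple[float, float], Tuple[float, float]]]
    status: str
    diagnostics: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if self.status not in STATUSES:
            raise InvalidParameterError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class AssayProtocolMeta:
    """Wet-lab protocol constants (metadata only; never used in computation)."""

    dpph_concentration_uM: float = 2000.0
    drop_volume_uL: float = 15.0
    incubation_minutes: float = 60.0
    post_incubation_dilution: float = 1.0 / 20.0
    wavelength_nm: float = 517.0

    def __post_init__(self) -> None:
        for name in (
            "dpph_concentration_uM",
            "drop_volume_uL",
            "incubation_minutes",
            "post_incubation_dilution",
            "wavelength_nm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
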