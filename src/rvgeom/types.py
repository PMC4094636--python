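"""Core value types for bifurcation annotation and geometry.

Coordinate convention: 0-based raster frame, origin at the top-left corner,
``x`` = column (increases rightward), ``y`` = row (increases downward).
Angles are in degrees; ``axis_angle`` is measured from the +x axis toward +y.
Widths and distances are in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VESSEL_TYPES = ("arteriole", "venule")

#: Retinopathy grades in increasing severity order.
GRADES = ("NoDR", "MinimalNPDR", "SevereNPDR", "PDR")

VISITS = ("baseline", "penultimate", "final")


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D coordinates must be finite, got {self}")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class RectangleSeed:
    """A rectangle aligned with a vessel segment centerline.

    ``center`` sits on the centerline, ``axis_angle`` (degrees) gives the
    centerline direction, ``length`` the along-axis extent over which
    cross-sectional profiles are taken, ``initial_width`` a rough starting
    width used to size the perpendicular profile.
    """

    center: Point2D
    axis_angle: float
    length: float
    initial_width: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"seed length must be > 0, got {self.length}")
        if self.initial_width <= 0:
            raise ValueError(
                f"seed initial_width must be > 0, got {self.initial_width}"
            )


@dataclass(frozen=True)
class OnhReference:
    """Optic nerve head center and diameter, used to normalise distances."""

    center: Point2D
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"ONH diameter must be > 0, got {self.diameter}")


@dataclass(frozen=True)
class BifurcationAnnotation:
    """User-marked landmarks for one vascular bifurcation.

    Four centerline points (the junction apex plus the far endpoints of the
    parent and the two child segments) and one rectangle seed per segment,
    ordered (parent, child_a, child_b).
    """

    apex: Point2D
    parent_end: Point2D
    child_a_end: Point2D
    child_b_end: Point2D
    seeds: tuple[RectangleSeed, RectangleSeed, RectangleSeed]
    vessel_type: str
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = [self.apex, self.parent_end, self.child_a_end, self.child_b_end]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if pts[i] == pts[j]:
                    raise ValueError(
                        "annotation points must be pairwise distinct; "
                        f"points {i} and {j} coincide at {pts[i]}"
                    )
        if len(self.seeds) != 3:
            raise ValueError(f"exactly 3 seeds required, got {len(self.seeds)}")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(
                f"vessel_type must be one of {VESSEL_TYPES}, got {self.vessel_type!r}"
            )


@dataclass
class BifurcationGeometry:
    """All structural/geometric quantities measured at one bifurcation.

    ``d0 >= d1 >= d2`` after child-role assignment (the wider child is the
    "larger" child); ``theta = theta1 + theta2`` by construction.  ``chi`` is
    the junction exponent, ``nan`` when no finite root exists (with the reason
    recorded in ``chi_reason``).  The derived ratios ``jer``, ``asymmetry_ratio``
    and ``area_ratio`` follow the documented default formulas (see
    :func:`rvgeom.geometry.compute_derived_ratios`).
    """

    d0: float
    d1: float
    d2: float
    theta1: float
    theta2: float
    theta: float
    chi: float  # nan when undefined
    jer: float
    asymmetry_ratio: float
    area_ratio: float
    distance_ratio: float
    vessel_type: str
    chi_reason: str = ""
    usable: bool = True
    flags: tuple[str, ...] = field(default_factory=tuple)

    FIELD_ORDER = (
        "d0", "d1", "d2", "theta1", "theta2", "theta", "chi",
        "jer", "asymmetry_ratio", "area_ratio", "distance_ratio",
    )

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.FIELD_ORDER}
        out["vessel_type"] = self.vessel_type
        out["usable"] = self.usable
        out["chi_reason"] = self.chi_reason
        out["flags"] = ";".join(self.flags)
        return out


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates for one subject (one eye per subject)."""

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    diabetes_type: int  # 1 | 2
    duration: float  # months
    hypertension: bool
    high_cholesterol: bool
    grade: str  # one of GRADES
    progressor: bool | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female|male, got {self.sex!r}")
        if self.diabetes_type not in (1, 2):
            raise ValueError(f"diabetes_type must be 1|2, got {self.diabetes_type}")
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")


#: Columns every feature table (long format, one row per bifurcation) carries.
FEATURE_COLUMNS = [
    "patient_id", "image_id", "bifurcation_id", "vessel_type",
    "d0", "d1", "d2", "theta1", "theta2", "theta", "chi",
    "jer", "asymmetry_ratio", "area_ratio", "distance_ratio",
]

#: Measured geometry features analysed downstream.
GEOMETRY_FEATURES = [
    "d0", "d1", "d2", "theta", "theta1", "theta2", "chi",
]

WIDTH_FEATURES = ["d0", "d1", "d2"]
ANGLE_FEATURES = ["theta", "theta1", "theta2"]


def validate_feature_table(df) -> None:
    """Raise ``ValueError`` if *df* is missing feature-table columns or has
    duplicated (image_id, bifurcation_id) keys."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    dup = df.duplicated(subset=["image_id", "bifurcation_id"])
    if dup.any():
        raise ValueError(
            f"feature table has {int(dup.sum())} duplicated "
            "(image_id, bifurcation_id) rows"
        )
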