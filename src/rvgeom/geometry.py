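"""Per-bifurcation geometry: vessel widths, branching angles, junction exponent.

The measurement model mirrors the semi-manual "rectangle" technique used for
fundus photographs: a rectangle is aligned over each vessel segment's
centerline, intensity profiles are sampled perpendicular to the centerline at
several stations along the rectangle, and the vessel width is read off each
profile from sub-pixel edge crossings.  Vessels are assumed darker than the
background (as in the green channel of a fundus photograph); bright-vessel
imagery can be handled by flipping ``dark_vessels``.

Widths of the parent and the two children (d0 >= d1 >= d2), the branching
angles of the larger and smaller child against the extrapolated parent
direction (theta1, theta2, theta = theta1 + theta2), the junction exponent chi
solving d1^chi + d2^chi = d0^chi, derived optimality ratios and the
ONH-normalised distance ratio together form one :class:`BifurcationGeometry`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import (
    ContrastPolarityError,
    DegenerateAnnotationError,
    DomainError,
    MeasurementFailureError,
    OutOfBoundsError,
)
from .types import (
    BifurcationAnnotation,
    BifurcationGeometry,
    OnhReference,
    Point2D,
    RectangleSeed,
)

#: Sub-pixel sample spacing along perpendicular profiles (pixels).
PROFILE_SPACING = 0.25

#: Junction-exponent solver bracket and |f| tolerance.
CHI_BRACKET = (1e-3, 50.0)
CHI_FTOL = 1e-9


# ---------------------------------------------------------------------------
# profile extraction and width estimation
# ---------------------------------------------------------------------------

def extract_perpendicular_profiles(
    image: np.ndarray,
    seed: RectangleSeed,
    n_stations: int,
    spacing: float = PROFILE_SPACING,
) -> np.ndarray:
    """Sample intensity profiles perpendicular to a seed rectangle's axis.

    ``n_stations`` profiles are taken at evenly spaced stations along the
    rectangle length (centered on ``seed.center``), each sampled at ``spacing``
    pixel steps with bilinear interpolation and a half-length of twice the
    seed's initial width.

    Returns an array of shape (n_stations, n_samples).

    Raises
    ------
    OutOfBoundsError
        if any sample falls outside the image, naming the seed.
    """
    if n_stations < 1:
        raise ValueError(f"n_stations must be >= 1, got {n_stations}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    h, w = img.shape

    a = math.radians(seed.axis_angle)
    ux, uy = math.cos(a), math.sin(a)          # along-axis direction
    nx, ny = -uy, ux                            # perpendicular direction

    if n_stations == 1:
        t = np.array([0.0])
    else:
        t = np.linspace(-seed.length / 2.0, seed.length / 2.0, n_stations)

    half = 2.0 * seed.initial_width
    k = int(math.ceil(half / spacing))
    s = np.arange(-k, k + 1) * spacing

    xs = seed.center.x + t[:, None] * ux + s[None, :] * nx
    ys = seed.center.y + t[:, None] * uy + s[None, :] * ny

    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise OutOfBoundsError(
            f"seed {seed.label or seed} rectangle exits image bounds "
            f"({h}x{w}): x in [{xs.min():.1f}, {xs.max():.1f}], "
            f"y in [{ys.min():.1f}, {ys.max():.1f}]"
        )

    vals = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return vals.reshape(xs.shape)


def _profile_width(
    profile: np.ndarray,
    method: str,
    spacing: float,
    dark_vessels: bool,
) -> float:
    """Edge-to-edge width (pixels) of the single vessel dip in one profile."""
    p = np.asarray(profile, dtype=float)
    if not dark_vessels:
        p = -p
    m = p.size
    if m < 8:
        raise MeasurementFailureError(f"profile too short ({m} samples)")

    k = max(1, int(round(m * 0.125)))  # outer 25% of samples, split over both ends
    background = float(np.median(np.concatenate([p[:k], p[-k:]])))
    lo, hi = m // 4, m - m // 4        # central 50%
    central = p[lo:hi]
    core = float(central.min())
    i_core = lo + int(np.argmin(central))

    depth = background - core
    bright_excursion = float(central.max()) - background
    if bright_excursion > max(depth, 1e-9):
        raise ContrastPolarityError(
            "profile is dominated by a bright excursion; expected a dark vessel"
        )
    if depth <= 1e-9:
        raise MeasurementFailureError(
            "flat profile: no vessel dip below background"
        )

    if method == "rectangle_halfheight":
        thr = (background + core) / 2.0
    elif method == "fwhm":
        # half-maximum of the background-minus-profile depth curve, with the
        # peak refined by a local parabola through the three deepest samples
        peak = depth
        if 0 < i_core < m - 1:
            y0, y1, y2 = (background - p[i_core - 1],
                          background - p[i_core],
                          background - p[i_core + 1])
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                peak = y1 - (y0 - y2) ** 2 / (8 * denom)
        thr = background - peak / 2.0
    else:
        raise ValueError(f"unknown width method {method!r}")

    # walk outward from the core minimum to the first threshold crossing on
    # each side; linear interpolation gives a sub-pixel edge position
    def _cross(direction: int) -> float:
        j = i_core
        while 0 <= j + direction < m:
            a, b = p[j], p[j + direction]
            if a < thr <= b:
                return j + direction * (thr - a) / (b - a)
            j += direction
        raise MeasurementFailureError(
            "no edge crossing found on "
            + ("right" if direction > 0 else "left")
            + " side of vessel dip"
        )

    left = _cross(-1)
    right = _cross(+1)
    return (right - left) * spacing


def estimate_segment_width(
    profiles: Sequence[np.ndarray] | np.ndarray,
    method: str = "rectangle_halfheight",
    spacing: float = PROFILE_SPACING,
    dark_vessels: bool = True,
    manual_edges: tuple[float, float] | None = None,
) -> float:
    """Vessel width (pixels) averaged across a segment's station profiles.

    ``method="rectangle_halfheight"`` locates, per profile, the sub-pixel
    crossings of the mid-level between the local background (median of the
    outer 25% of samples) and the vessel core (minimum of the central 50%).
    ``method="fwhm"`` uses the half-maximum of the background-minus-profile
    depth curve instead, with a parabolic refinement of the peak depth.

    ``manual_edges`` overrides the automatic edge rule with caller-supplied
    edge positions (pixels along the profile), mirroring the observer-adapted
    width of the interactive tool the procedure descends from.
    """
    if manual_edges is not None:
        left, right = manual_edges
        if right <= left:
            raise ValueError("manual_edges must satisfy right > left")
        return float(right - left)
    widths = [_profile_width(p, method, spacing, dark_vessels) for p in profiles]
    if not widths:
        raise MeasurementFailureError("no profiles supplied")
    return float(np.mean(widths))


# ---------------------------------------------------------------------------
# angles and roles
# ---------------------------------------------------------------------------

def _angle_between(v: tuple[float, float], w: tuple[float, float]) -> float:
    nv = math.hypot(*v)
    nw = math.hypot(*w)
    c = (v[0] * w[0] + v[1] * w[1]) / (nv * nw)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def compute_branch_angles(
    apex: Point2D,
    parent_end: Point2D,
    child_a_end: Point2D,
    child_b_end: Point2D,
) -> tuple[float, float, float, bool]:
    """Branching angles of the two children against the extrapolated parent.

    The parent flow direction is ``apex - parent_end`` extrapolated through
    the apex; each child angle is the unsigned angle in [0, 180] between the
    child vector (``end - apex``) and that direction.  Returns
    ``(angle_a, angle_b, total, same_side_flag)`` where ``total`` is the sum
    and ``same_side_flag`` marks both children lying on the same side of the
    parent axis (in which case the total differs from the inter-child angle).
    """
    vp = (apex.x - parent_end.x, apex.y - parent_end.y)
    va = (child_a_end.x - apex.x, child_a_end.y - apex.y)
    vb = (child_b_end.x - apex.x, child_b_end.y - apex.y)
    for name, v in (("parent", vp), ("child_a", va), ("child_b", vb)):
        if math.hypot(*v) == 0.0:
            raise DegenerateAnnotationError(
                f"zero-length {name} centerline vector at apex {apex}"
            )
    angle_a = _angle_between(va, vp)
    angle_b = _angle_between(vb, vp)
    cross_a = vp[0] * va[1] - vp[1] * va[0]
    cross_b = vp[0] * vb[1] - vp[1] * vb[0]
    same_side = (cross_a * cross_b) > 0.0
    return angle_a, angle_b, angle_a + angle_b, same_side


def assign_child_roles(
    width_a: float, angle_a: float, width_b: float, angle_b: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Map the two children onto (d1, theta1) = larger and (d2, theta2) = smaller.

    The strictly wider child takes the larger role; an exact width tie is
    broken deterministically by the smaller deflection angle.
    """
    if width_a <= 0 or width_b <= 0:
        raise DomainError(f"child widths must be > 0, got {width_a}, {width_b}")
    a, b = (width_a, angle_a), (width_b, angle_b)
    if width_a > width_b:
        return a, b
    if width_b > width_a:
        return b, a
    return (a, b) if angle_a <= angle_b else (b, a)


# ---------------------------------------------------------------------------
# junction exponent and derived ratios
# ---------------------------------------------------------------------------

def _check_widths(d0: float, d1: float, d2: float) -> None:
    if d0 <= 0 or d1 <= 0 or d2 <= 0:
        raise DomainError(f"widths must be > 0, got ({d0}, {d1}, {d2})")


def solve_junction_exponent(
    d0: float,
    d1: float,
    d2: float,
    bracket: tuple[float, float] = CHI_BRACKET,
    ftol: float = CHI_FTOL,
) -> float | None:
    """Junction exponent chi solving ``d1^chi + d2^chi = d0^chi``.

    For ``d0 > d1 >= d2 > 0`` the scaled residual
    ``f(chi) = (d1/d0)^chi + (d2/d0)^chi - 1`` is strictly decreasing with a
    unique positive root, found by bracketed bisection.  When ``d0 <= d1``
    (or the root lies beyond the bracket) no finite root exists and ``None``
    is returned.
    """
    _check_widths(d0, d1, d2)
    if d0 <= d1:
        return None
    r1, r2 = d1 / d0, d2 / d0

    def f(chi: float) -> float:
        return r1 ** chi + r2 ** chi - 1.0

    lo, hi = bracket
    if f(lo) <= 0.0 or f(hi) >= 0.0:
        return None  # root outside bracket (extreme near-equal widths)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= ftol:
            return mid
        if fm > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


def solve_junction_exponent_many(
    d0: np.ndarray, d1: np.ndarray, d2: np.ndarray
) -> np.ndarray:
    """Vectorised junction exponents; ``nan`` where no finite root exists.

    Same bracket/iteration scheme as :func:`solve_junction_exponent`, applied
    simultaneously to arrays (used by the cohort generator).
    """
    d0 = np.asarray(d0, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d0 <= 0) or np.any(d1 <= 0) or np.any(d2 <= 0):
        raise DomainError("widths must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = np.log(d1 / d0)
        l2 = np.log(d2 / d0)

    def f(chi: np.ndarray) -> np.ndarray:
        return np.exp(chi * l1) + np.exp(chi * l2) - 1.0

    lo = np.full(d0.shape, CHI_BRACKET[0])
    hi = np.full(d0.shape, CHI_BRACKET[1])
    valid = (d0 > d1) & (f(lo) > 0.0) & (f(hi) < 0.0)
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    out = 0.5 * (lo + hi)
    out[~valid] = np.nan
    return out


def compute_derived_ratios(d0: float, d1: float, d2: float) -> tuple[float, float, float]:
    """Derived optimality ratios ``(jer, asymmetry_ratio, area_ratio)``.

    Definitions (implementation choices, fixed and documented here since the
    field uses several variants):

    - ``jer`` (junction exponent ratio): ``d0 / (d1^3 + d2^3)^(1/3)`` — 1 for
      a Murray-optimal (cube-law) junction;
    - ``asymmetry_ratio``: ``(d2/d1)^2`` — 1 for symmetric children;
    - ``area_ratio``: ``(d1^2 + d2^2) / d0^2`` — combined child over parent
      cross-sectional area.
    """
    _check_widths(d0, d1, d2)
    jer = d0 / (d1 ** 3 + d2 ** 3) ** (1.0 / 3.0)
    asymmetry = (d2 / d1) ** 2
    area = (d1 ** 2 + d2 ** 2) / d0 ** 2
    return jer, asymmetry, area


def distance_ratio(apex: Point2D, onh: OnhReference) -> float:
    """Apex-to-ONH-center distance over the ONH diameter (dimensionless)."""
    return apex.distance_to(onh.center) / onh.diameter


# ---------------------------------------------------------------------------
# full measurement
# ---------------------------------------------------------------------------

def measure_bifurcation(
    image: np.ndarray,
    annotation: BifurcationAnnotation,
    onh: OnhReference,
    n_stations: int = 7,
    method: str = "rectangle_halfheight",
    dark_vessels: bool = True,
) -> BifurcationGeometry:
    """Measure one annotated bifurcation on an image.

    Composes profile extraction, per-segment width estimation, branch-angle
    computation, child-role assignment, junction exponent, derived ratios and
    the ONH distance ratio.  A failed sub-step flags the record unusable
    (``usable=False`` with a reason in ``flags``) instead of aborting, so a
    bad junction never sinks the rest of an image.
    """
    flags: list[str] = []
    seg_names = ("parent", "child_a", "child_b")
    widths: list[float] = []
    for name, seed in zip(seg_names, annotation.seeds):
        try:
            profiles = extract_perpendicular_profiles(image, seed, n_stations)
            widths.append(
                estimate_segment_width(profiles, method=method, dark_vessels=dark_vessels)
            )
        except (OutOfBoundsError, MeasurementFailureError, ContrastPolarityError) as e:
            flags.append(f"{name}: {e}")
            widths.append(math.nan)

    try:
        angle_a, angle_b, _, same_side = compute_branch_angles(
            annotation.apex, annotation.parent_end,
            annotation.child_a_end, annotation.child_b_end,
        )
    except DegenerateAnnotationError as e:
        flags.append(f"angles: {e}")
        angle_a = angle_b = math.nan
        same_side = False
    if same_side:
        flags.append("angles: children on same side of parent axis")

    d0, wa, wb = widths
    if math.isfinite(wa) and math.isfinite(wb) and math.isfinite(angle_a):
        (d1, theta1), (d2, theta2) = assign_child_roles(wa, angle_a, wb, angle_b)
    else:
        d1 = d2 = theta1 = theta2 = math.nan

    chi = math.nan
    chi_reason = ""
    jer = asymmetry = area = math.nan
    if math.isfinite(d0) and math.isfinite(d1) and math.isfinite(d2):
        if d0 < d1:
            flags.append("widths: parent narrower than larger child")
        root = solve_junction_exponent(d0, d1, d2) if d0 > d1 else None
        if root is None:
            chi_reason = "no finite root"
        else:
            chi = root
        if d0 >= d1 >= d2 > 0:
            jer, asymmetry, area = compute_derived_ratios(d0, d1, d2)

    usable = (
        math.isfinite(d0)
        and math.isfinite(d1)
        and math.isfinite(d2)
        and math.isfinite(theta1)
    )

    return BifurcationGeometry(
        d0=d0, d1=d1, d2=d2,
        theta1=theta1, theta2=theta2, theta=theta1 + theta2,
        chi=chi, chi_reason=chi_reason,
        jer=jer, asymmetry_ratio=asymmetry, area_ratio=area,
        distance_ratio=distance_ratio(annotation.apex, onh),
        vessel_type=annotation.vessel_type,
        usable=usable,
        flags=tuple(flags),
    )
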