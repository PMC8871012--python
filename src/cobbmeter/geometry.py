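"""Cobb-angle geometry from scored vertebral corner landmarks.

The coronal Cobb angle is the clinical standard for grading scoliosis: it is
the angle between the superior endplate of the most-tilted vertebra above the
curve apex and the inferior endplate of the most-tilted vertebra below it.
Given up to 17 vertebrae, each located by its four corner landmarks and a
detection score, this module runs the full measurement chain:

1. drop low-confidence boxes (score threshold, default 0.5);
2. reject boxes whose horizontal center strays more than half a box width
   from the centers of their vertical neighbours (anatomically, adjacent
   vertebrae cannot be far apart laterally);
3. re-impute rejected boxes from a polynomial fit of the remaining centers;
4. locate the apex as the most laterally displaced vertebra relative to the
   chord joining the first and last centers, with convexity decided by the
   left/right inter-vertebral gap profile;
5. pick the end vertebrae as the most tilted endplates above and below the
   apex, and report the angle between those two endplate lines.

Coordinates are image pixels: origin top-left, x grows rightward, y grows
downward, indices are 0-based, vertebrae are ordered superior to inferior.
Endplate tilt is measured left corner to right corner and is positive when
the right corner sits lower on screen (clockwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Point2D",
    "VertebraBox",
    "SpineSequence",
    "GapProfile",
    "CobbResult",
    "MeasurementInfeasibleError",
    "DegenerateBoxError",
    "filter_by_score",
    "detect_outliers",
    "impute_boxes",
    "edge_tilt",
    "gap_profile",
    "find_apex",
    "select_end_vertebrae",
    "measure_cobb",
]

#: Perpendicular distance (px) below which a spine is treated as straight.
ZERO_CURVE_TOL_PX = 1.0


class MeasurementInfeasibleError(ValueError):
    """Raised when too few usable vertebrae remain for a Cobb measurement."""


class DegenerateBoxError(ValueError):
    """Raised when a vertebra box has coincident corners."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class VertebraBox:
    """One vertebra: four corner landmarks, center, and detection score.

    The center equals the mean of the four corners unless the box was
    imputed, in which case it comes from the centerline fit.
    """

    top_left: Point2D
    top_right: Point2D
    bottom_left: Point2D
    bottom_right: Point2D
    center: Point2D = field(default=None)  # type: ignore[assignment]
    score: float = 1.0
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.center is None:
            cx = (self.top_left.x + self.top_right.x
                  + self.bottom_left.x + self.bottom_right.x) / 4.0
            cy = (self.top_left.y + self.top_right.y
                  + self.bottom_left.y + self.bottom_right.y) / 4.0
            object.__setattr__(self, "center", Point2D(cx, cy))
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        """Mean of the top and bottom edge lengths."""
        top = math.dist((self.top_left.x, self.top_left.y),
                        (self.top_right.x, self.top_right.y))
        bot = math.dist((self.bottom_left.x, self.bottom_left.y),
                        (self.bottom_right.x, self.bottom_right.y))
        return (top + bot) / 2.0

    @property
    def height(self) -> float:
        """Mean of the left and right edge lengths."""
        left = math.dist((self.top_left.x, self.top_left.y),
                         (self.bottom_left.x, self.bottom_left.y))
        right = math.dist((self.top_right.x, self.top_right.y),
                          (self.bottom_right.x, self.bottom_right.y))
        return (left + right) / 2.0

    def corners(self) -> tuple[Point2D, Point2D, Point2D, Point2D]:
        return (self.top_left, self.top_right, self.bottom_left, self.bottom_right)


@dataclass(frozen=True)
class SpineSequence:
    """Ordered superior-to-inferior sequence of vertebra boxes for one image."""

    boxes: tuple[VertebraBox, ...]
    image_width: int = 512
    image_height: int = 1024

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        ys = [b.center.y for b in self.boxes]
        if any(a >= b for a, b in zip(ys, ys[1:])):
            raise ValueError("boxes must be strictly ordered by increasing center y")
        if len(self.boxes) > 17:
            raise ValueError(f"{len(self.boxes)} boxes exceed the 17-vertebra maximum")

    def __len__(self) -> int:
        return len(self.boxes)

    def __getitem__(self, i: int) -> VertebraBox:
        return self.boxes[i]


@dataclass(frozen=True)
class GapProfile:
    """Adjacent-pair corner gaps along the left and right sides of the spine."""

    left_gaps: tuple[float, ...]
    right_gaps: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.left_gaps) != len(self.right_gaps):
            raise ValueError("left/right gap lists must have equal length")


@dataclass(frozen=True)
class CobbResult:
    angle_deg: float
    angle_deg_rounded: int
    apex_index: int
    superior_index: int
    inferior_index: int
    direction: str  # "left-convex" | "right-convex" | "straight"
    tilt_sup_deg: float
    tilt_inf_deg: float
    zero_curve: bool = False
    n_filtered: int = 0
    outlier_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.superior_index <= self.apex_index <= self.inferior_index:
            raise ValueError("end vertebrae must bracket the apex")
        if not 0.0 <= self.angle_deg < 180.0:
            raise ValueError(f"angle {self.angle_deg} outside [0, 180)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def filter_by_score(seq: SpineSequence, threshold: float = 0.5) -> SpineSequence:
    """Keep only boxes whose detection score exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    kept = tuple(b for b in seq.boxes if b.score > threshold)
    if len(kept) < 5:
        raise MeasurementInfeasibleError(
            f"only {len(kept)} boxes above score {threshold}; at least 5 required"
        )
    return SpineSequence(kept, seq.image_width, seq.image_height)


def detect_outliers(seq: SpineSequence) -> list[int]:
    """Indices of boxes laterally inconsistent with their vertical neighbours.

    A box is an outlier when its x-center lies more than half its width from
    the mean x-center of its two nearest non-outlier neighbours; the first
    and last boxes are compared to their single neighbour.  Violations are
    resolved greedily, worst first: one displaced vertebra also perturbs the
    neighbour test of the boxes beside it, so after flagging the worst
    offender the remaining boxes are re-checked against the nearest boxes
    still considered good.
    """
    n = len(seq)
    if n < 3:
        raise ValueError("outlier detection needs at least 3 boxes")
    xc = [b.center.x for b in seq.boxes]
    flagged: set[int] = set()
    while True:
        good = [i for i in range(n) if i not in flagged]
        worst, worst_excess = None, 0.0
        for pos, i in enumerate(good):
            below = good[pos + 1] if pos + 1 < len(good) else None
            above = good[pos - 1] if pos > 0 else None
            if above is not None and below is not None:
                ref = (xc[above] + xc[below]) / 2.0
            elif above is not None:
                ref = xc[above]
            elif below is not None:
                ref = xc[below]
            else:
                continue
            excess = abs(xc[i] - ref) - seq[i].width / 2.0
            if excess > 0 and excess > worst_excess:
                worst, worst_excess = i, excess
        if worst is None:
            return sorted(flagged)
        flagged.add(worst)


#: Good boxes used per local centerline fit; a window keeps the cubic
#: accurate on a sinusoidal spine, where a global cubic drifts by pixels.
_FIT_WINDOW = 6


def _fit_centerline(good: list[VertebraBox], at_y: float):
    """Least-squares cubic x(y) through the good-box centers nearest at_y.

    Cubic when four or more centers are available, otherwise a linear
    fallback.  Returns (poly, degraded) where degraded flags the fallback.
    """
    nearest = sorted(good, key=lambda b: abs(b.center.y - at_y))[:_FIT_WINDOW]
    ys = np.array([b.center.y for b in nearest])
    xs = np.array([b.center.x for b in nearest])
    if len(nearest) >= 4:
        return np.polynomial.Polynomial.fit(ys, xs, 3), False
    return np.polynomial.Polynomial.fit(ys, xs, 1), True


def impute_boxes(seq: SpineSequence, bad: list[int]) -> SpineSequence:
    """Replace outlier boxes using the fitted centerline and their neighbours.

    Each bad box keeps its vertical position but takes its center x from a
    cubic polynomial fit of the good centers (x as a function of y); width,
    height and endplate tilt are linearly interpolated between the nearest
    good boxes above and below.
    """
    if not bad:
        return seq
    if len(bad) > 2:
        raise MeasurementInfeasibleError(
            f"{len(bad)} boxes need imputation; at most 2 supported"
        )
    bad_set = set(bad)
    good_idx = [i for i in range(len(seq)) if i not in bad_set]
    good = [seq[i] for i in good_idx]
    if len(good) < 5:
        raise MeasurementInfeasibleError(
            f"only {len(good)} good boxes remain; at least 5 required"
        )
    def interp_attr(i: int, attr) -> float:
        below = [j for j in good_idx if j > i]
        above = [j for j in good_idx if j < i]
        if above and below:
            ja, jb = above[-1], below[0]
            ya, yb = seq[ja].center.y, seq[jb].center.y
            t = (seq[i].center.y - ya) / (yb - ya)
            return (1 - t) * attr(seq[ja]) + t * attr(seq[jb])
        j = below[0] if below else above[-1]
        return attr(seq[j])

    new_boxes: list[VertebraBox] = []
    for i, box in enumerate(seq.boxes):
        if i not in bad_set:
            new_boxes.append(box)
            continue
        cy = box.center.y
        poly, _ = _fit_centerline(good, cy)
        cx = float(poly(cy))
        w = interp_attr(i, lambda b: b.width)
        h = interp_attr(i, lambda b: b.height)
        tilt = interp_attr(i, lambda b: edge_tilt(b, "top"))
        new_boxes.append(_box_from_pose(cx, cy, w, h, tilt, box.score))
    return SpineSequence(tuple(new_boxes), seq.image_width, seq.image_height)


def _box_from_pose(cx: float, cy: float, w: float, h: float,
                   tilt_deg: float, score: float) -> VertebraBox:
    """Build a parallelogram box from center, size and endplate tilt."""
    phi = math.radians(tilt_deg)
    ux, uy = math.cos(phi), math.sin(phi)        # along endplate, left→right
    vx, vy = -math.sin(phi), math.cos(phi)       # toward the inferior edge
    hw, hh = w / 2.0, h / 2.0
    return VertebraBox(
        top_left=Point2D(cx - hw * ux - hh * vx, cy - hw * uy - hh * vy),
        top_right=Point2D(cx + hw * ux - hh * vx, cy + hw * uy - hh * vy),
        bottom_left=Point2D(cx - hw * ux + hh * vx, cy - hw * uy + hh * vy),
        bottom_right=Point2D(cx + hw * ux + hh * vx, cy + hw * uy + hh * vy),
        center=Point2D(cx, cy),
        score=score,
        imputed=True,
    )


def edge_tilt(box: VertebraBox, edge: str) -> float:
    """Endplate inclination in signed degrees, left corner to right corner.

    Positive when the right corner is lower on screen (y grows downward).
    """
    if edge == "top":
        a, b = box.top_left, box.top_right
    elif edge == "bottom":
        a, b = box.bottom_left, box.bottom_right
    else:
        raise ValueError(f"edge must be 'top' or 'bottom', got {edge!r}")
    dx, dy = b.x - a.x, b.y - a.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateBoxError(f"coincident {edge} corners at ({a.x}, {a.y})")
    return math.degrees(math.atan2(dy, dx))


def gap_profile(seq: SpineSequence) -> GapProfile:
    """Left/right corner-to-corner distances between adjacent vertebrae.

    For each adjacent pair the left gap joins the bottom-left corner of the
    upper box to the top-left corner of the lower one; right gaps pair the
    corresponding right corners.  On a curved spine the concave side
    accumulates the smaller total gap, which is what decides convexity.
    """
    if len(seq) < 2:
        raise ValueError("gap profile needs at least 2 boxes")
    left, right = [], []
    for up, lo in zip(seq.boxes, seq.boxes[1:]):
        left.append(math.dist((up.bottom_left.x, up.bottom_left.y),
                              (lo.top_left.x, lo.top_left.y)))
        right.append(math.dist((up.bottom_right.x, up.bottom_right.y),
                               (lo.top_right.x, lo.top_right.y)))
    return GapProfile(tuple(left), tuple(right))


def find_apex(seq: SpineSequence) -> tuple[int, str, bool]:
    """Locate the curve apex and its convexity side.

    The apex is the vertebral center with the largest perpendicular distance
    from the chord joining the first and last centers (the most laterally
    displaced vertebra).  Returns (apex_index, direction, zero_curve); when
    every center lies within ``ZERO_CURVE_TOL_PX`` of the chord the spine is
    flagged straight and the middle index is returned.
    """
    n = len(seq)
    if n < 5:
        raise MeasurementInfeasibleError(f"apex search needs ≥ 5 boxes, got {n}")
    p0 = np.array([seq[0].center.x, seq[0].center.y])
    p1 = np.array([seq[-1].center.x, seq[-1].center.y])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    dists = np.empty(n)
    for i, b in enumerate(seq.boxes):
        v = np.array([b.center.x, b.center.y]) - p0
        dists[i] = abs(chord[0] * v[1] - chord[1] * v[0]) / norm
    if dists.max() < ZERO_CURVE_TOL_PX:
        return n // 2, "straight", True
    apex = int(np.argmax(dists))  # argmax ties break toward the superior index
    gp = gap_profile(seq)
    direction = "left-convex" if sum(gp.left_gaps) > sum(gp.right_gaps) else "right-convex"
    return apex, direction, False


def select_end_vertebrae(seq: SpineSequence, apex_index: int) -> tuple[int, int]:
    """Most-tilted vertebrae above and below the apex.

    The superior end maximizes |top-endplate tilt| over indices ≤ apex; the
    inferior end maximizes |bottom-endplate tilt| over indices ≥ apex.  The
    apex itself is eligible on both sides; ties go to the vertebra farther
    from the apex.
    """
    if not 0 <= apex_index < len(seq):
        raise ValueError(f"apex index {apex_index} out of range")
    sup = apex_index
    best = -1.0
    for i in range(apex_index + 1):  # scanning away-from-apex last would flip ties
        t = abs(edge_tilt(seq[i], "top"))
        if t > best:
            best, sup = t, i
    inf = apex_index
    best = -1.0
    for i in range(len(seq) - 1, apex_index - 1, -1):
        t = abs(edge_tilt(seq[i], "bottom"))
        if t > best:
            best, inf = t, i
    return sup, inf


def measure_cobb(seq: SpineSequence, score_threshold: float = 0.5) -> CobbResult:
    """Full measurement chain from a raw scored sequence to a Cobb angle.

    Runs score filtering, lateral-outlier rejection, imputation, apex
    detection and end-vertebra selection; the angle is the absolute
    difference between the superior top-endplate tilt and the inferior
    bottom-endplate tilt.  All reported indices refer to the
    post-imputation sequence.
    """
    filtered = filter_by_score(seq, score_threshold)
    n_filtered = len(seq) - len(filtered)
    outliers = detect_outliers(filtered)
    if len(outliers) > 2:
        raise MeasurementInfeasibleError(
            f"{len(outliers)} lateral outliers; at most 2 can be re-imputed"
        )
    clean = impute_boxes(filtered, outliers)
    apex, direction, zero_curve = find_apex(clean)
    if zero_curve:
        mid = len(clean) // 2
        return CobbResult(
            angle_deg=0.0, angle_deg_rounded=0, apex_index=mid,
            superior_index=mid, inferior_index=mid, direction=direction,
            tilt_sup_deg=0.0, tilt_inf_deg=0.0, zero_curve=True,
            n_filtered=n_filtered, outlier_indices=tuple(outliers),
        )
    sup, inf = select_end_vertebrae(clean, apex)
    tilt_sup = edge_tilt(clean[sup], "top")
    tilt_inf = edge_tilt(clean[inf], "bottom")
    angle = abs(tilt_sup - tilt_inf)
    return CobbResult(
        angle_deg=angle,
        angle_deg_rounded=_round_half_away(angle),
        apex_index=apex,
        superior_index=sup,
        inferior_index=inf,
        direction=direction,
        tilt_sup_deg=tilt_sup,
        tilt_inf_deg=tilt_inf,
        zero_curve=False,
        n_filtered=n_filtered,
        outlier_indices=tuple(outliers),
    )
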