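"""Keypoint-detection support math: focal loss, landmark error, box decoding.

The landmark detector in the full pipeline predicts, at a downsampled
stride, a center heatmap per vertebra plus sub-pixel center offsets and
eight corner-offset channels (tl, tr, bl, br x x, y).  This module holds the
pieces of that machinery that are pure math and usable without any trained
network:

* the penalty-reduced focal loss used for heatmap training, where cells at a
  ground-truth peak (tau = 1) contribute (1 - rho)^2 log rho and all other
  cells contribute (1 - tau)^4 rho^2 log(1 - rho), averaged over the map and
  negated;
* the mean Euclidean landmark localization error between detected and
  ground-truth point sets;
* encoding of a vertebra-box sequence into center/offset maps (Gaussian
  peaks, sigma 2 cells) and the inverse decoding via top-k peak picking with
  3x3 non-maximum suppression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Point2D, SpineSequence, VertebraBox

__all__ = ["HeatmapPair", "LandmarkSet", "OffsetMaps",
           "focal_loss", "landmark_error", "encode_boxes", "decode_boxes",
           "save_offset_maps", "load_offset_maps"]

#: Probability clamp keeping log() finite in the focal loss.
PROB_EPS = 1e-7

#: Gaussian peak width (grid cells) used when encoding ground-truth heatmaps.
ENCODE_SIGMA = 2.0

_CORNER_ORDER = ("tl", "tr", "bl", "br")


@dataclass(frozen=True)
class HeatmapPair:
    prediction: np.ndarray   # rho, clamped into (0, 1)
    ground_truth: np.ndarray  # tau in [0, 1], exactly 1 at peaks

    def __post_init__(self) -> None:
        p = np.asarray(self.prediction, dtype=float)
        t = np.asarray(self.ground_truth, dtype=float)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
        object.__setattr__(self, "prediction", np.clip(p, PROB_EPS, 1 - PROB_EPS))
        object.__setattr__(self, "ground_truth", t)


@dataclass(frozen=True)
class LandmarkSet:
    points: tuple[Point2D, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 1:
            raise ValueError("landmark set cannot be empty")

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @classmethod
    def from_sequence(cls, seq: SpineSequence) -> "LandmarkSet":
        pts = []
        for b in seq.boxes:
            pts.extend(b.corners())
        return cls(tuple(pts))


@dataclass(frozen=True)
class OffsetMaps:
    """Center heatmap plus sub-cell center and corner displacement channels."""

    center_heatmap: np.ndarray           # (H, W)
    center_offset: np.ndarray            # (H, W, 2) pixels, x then y
    corner_offsets: np.ndarray           # (H, W, 8) pixels, tl,tr,bl,br x x,y
    stride: int

    def __post_init__(self) -> None:
        hm = np.asarray(self.center_heatmap, dtype=float)
        co = np.asarray(self.center_offset, dtype=float)
        ko = np.asarray(self.corner_offsets, dtype=float)
        if co.shape != hm.shape + (2,) or ko.shape != hm.shape + (8,):
            raise ValueError("offset channels must share the heatmap's spatial shape")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        object.__setattr__(self, "center_heatmap", hm)
        object.__setattr__(self, "center_offset", co)
        object.__setattr__(self, "corner_offsets", ko)


def focal_loss(h: HeatmapPair) -> float:
    """Penalty-reduced focal loss averaged over all map cells, >= 0.

    Cells where tau = 1 are positives; every other cell is a negative whose
    penalty is down-weighted by (1 - tau)^4, so near-peak cells — where tau
    is close to but not exactly 1 — are punished only mildly for a high
    prediction.
    """
    rho = h.prediction
    tau = h.ground_truth
    pos = tau == 1.0
    terms = np.where(
        pos,
        (1.0 - rho) ** 2 * np.log(rho),
        (1.0 - tau) ** 4 * rho ** 2 * np.log(1.0 - rho),
    )
    return float(-terms.mean())


def landmark_error(detected: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean Euclidean distance between index-aligned landmark pairs, pixels."""
    d = detected.as_array()
    p = truth.as_array()
    if d.shape != p.shape:
        raise ValueError(f"count mismatch: {len(d)} detected vs {len(p)} truth")
    return float(np.linalg.norm(d - p, axis=1).mean())


def encode_boxes(seq: SpineSequence, stride: int = 4,
                 sigma: float = ENCODE_SIGMA) -> OffsetMaps:
    """Rasterize a box sequence into ground-truth center/offset maps.

    Each vertebra center lands in the grid cell floor(center / stride); that
    cell carries tau = 1 with a Gaussian skirt (sigma in cells) around it,
    the sub-cell remainder in the center-offset channels, and the
    center-to-corner displacements (in pixels) in the corner channels.
    """
    gh = math.ceil(seq.image_height / stride)
    gw = math.ceil(seq.image_width / stride)
    hm = np.zeros((gh, gw))
    coff = np.zeros((gh, gw, 2))
    korner = np.zeros((gh, gw, 8))
    yy, xx = np.mgrid[0:gh, 0:gw]
    for box in seq.boxes:
        cx, cy = box.center.x / stride, box.center.y / stride
        gx, gy = int(cx), int(cy)
        if not (0 <= gx < gw and 0 <= gy < gh):
            raise ValueError("box center outside the image grid")
        splat = np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2.0 * sigma ** 2))
        hm = np.maximum(hm, splat)
        hm[gy, gx] = 1.0
        coff[gy, gx] = (box.center.x - gx * stride, box.center.y - gy * stride)
        for ci, corner in enumerate(box.corners()):
            korner[gy, gx, 2 * ci] = corner.x - box.center.x
            korner[gy, gx, 2 * ci + 1] = corner.y - box.center.y
    return OffsetMaps(hm, coff, korner, stride)


def _nms_peaks(hm: np.ndarray) -> np.ndarray:
    """Boolean mask of cells that are 3x3 local maxima (plateaus keep all)."""
    from scipy.ndimage import maximum_filter

    localmax = maximum_filter(hm, size=3, mode="constant", cval=-np.inf)
    return hm >= localmax


def decode_boxes(maps: OffsetMaps, k: int = 17,
                 image_width: int | None = None,
                 image_height: int | None = None) -> SpineSequence:
    """Recover a scored box sequence from center/offset maps.

    Takes the top-k 3x3 non-maximum-suppressed peaks of the center heatmap,
    places each center at peak_cell * stride + center_offset, adds the
    corner displacements, and orders the boxes by center y.  The heatmap
    value at the peak becomes the detection score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hm = maps.center_heatmap
    peaks = np.argwhere(_nms_peaks(hm) & (hm > 0))
    if len(peaks) == 0:
        raise ValueError("no peaks in the center heatmap")
    scores = hm[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-scores, kind="stable")[:k]
    if len(order) < k:
        warnings.warn(f"only {len(order)} peaks found; {k} requested")
    boxes = []
    for idx in order:
        gy, gx = peaks[idx]
        ox, oy = maps.center_offset[gy, gx]
        cx = gx * maps.stride + ox
        cy = gy * maps.stride + oy
        ko = maps.corner_offsets[gy, gx]
        pts = {name: Point2D(cx + ko[2 * ci], cy + ko[2 * ci + 1])
               for ci, name in enumerate(_CORNER_ORDER)}
        boxes.append(VertebraBox(pts["tl"], pts["tr"], pts["bl"], pts["br"],
                                 center=Point2D(cx, cy),
                                 score=float(np.clip(hm[gy, gx], 0.0, 1.0))))
    boxes.sort(key=lambda b: b.center.y)
    w = image_width if image_width is not None else maps.center_heatmap.shape[1] * maps.stride
    h = image_height if image_height is not None else maps.center_heatmap.shape[0] * maps.stride
    return SpineSequence(tuple(boxes), w, h)


def save_offset_maps(maps: OffsetMaps, path) -> None:
    """Write maps as an uncompressed NPZ archive with named arrays."""
    np.savez(path, center=maps.center_heatmap, coff=maps.center_offset,
             korner=maps.corner_offsets, stride=np.array(maps.stride))


def load_offset_maps(path) -> OffsetMaps:
    with np.load(path) as z:
        return OffsetMaps(z["center"], z["coff"], z["korner"], int(z["stride"]))
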