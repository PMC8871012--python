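"""Torso localization in radiographs with LBP histograms and boosted stumps.

Standing spine radiographs carry large empty margins and annotation burn-ins,
so the measurement pipeline first crops the image to the torso — roughly the
band from the seventh cervical vertebra down to the sacrum.  The detector is
deliberately classical: each sliding window is described by a 256-bin
histogram of 8-neighbour local binary pattern (LBP) codes, a cascade of
AdaBoost strong classifiers labels the window torso/background, and the crop
is the union of the positive windows.

The LBP code of a pixel thresholds its 8 circular neighbours (radius 1)
against the center — g(z) = 1 for z >= 0, else 0, so ties count as 1 — and
packs the bits as sum g(N_k - N_c) * 2^k with neighbours enumerated clockwise
from the top-left.  A strong classifier labels a window positive when the
beta-weighted votes of its decision stumps reach half the total weight:
sum_i alpha_i(X) log(1/beta_i) >= 1/2 sum_i log(1/beta_i), with
beta_i = eps_i / (1 - eps_i) from the weighted training error of round i.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LBPConfig", "WeakClassifier", "StrongClassifier", "Cascade",
    "DetectionWindow", "CropFailedError",
    "lbp_code", "lbp_code_map", "lbp_histogram",
    "strong_classify", "train_adaboost", "train_cascade",
    "sliding_window_detect", "crop_body",
]

# neighbour offsets (dy, dx) clockwise from the top-left neighbour
_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1))


class CropFailedError(RuntimeError):
    """No torso detected; the caller must supply a manual crop region."""


@dataclass(frozen=True)
class LBPConfig:
    n_points: int = 8
    radius: int = 1

    def __post_init__(self) -> None:
        if self.n_points < 4 or self.radius < 1:
            raise ValueError("need n_points >= 4 and radius >= 1")
        if (self.n_points, self.radius) != (8, 1):
            raise NotImplementedError("only the 8-point, radius-1 LBP is supported")


@dataclass(frozen=True)
class WeakClassifier:
    """Decision stump over one histogram bin with its boosting weight beta."""

    feature_index: int
    threshold: float
    polarity: int  # +1: vote 1 when feature > threshold; -1: when feature <= threshold
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie strictly in (0, 1)")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")

    def vote(self, features: np.ndarray) -> int:
        v = features[self.feature_index] > self.threshold
        return int(v) if self.polarity == 1 else int(not v)


@dataclass(frozen=True)
class StrongClassifier:
    weak: tuple[WeakClassifier, ...]

    def __post_init__(self) -> None:
        if len(self.weak) < 1:
            raise ValueError("strong classifier needs at least one round")
        object.__setattr__(self, "weak", tuple(self.weak))

    @property
    def n_rounds(self) -> int:
        return len(self.weak)


@dataclass(frozen=True)
class Cascade:
    """Strong classifiers applied in sequence; any negative stage rejects."""

    stages: tuple[StrongClassifier, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))

    def classify(self, features: np.ndarray) -> int:
        for stage in self.stages:
            if strong_classify(features, stage) == 0:
                return 0
        return 1


@dataclass(frozen=True)
class DetectionWindow:
    x: int
    y: int
    w: int
    h: int
    label: str = "positive"

    def iou(self, other: "DetectionWindow") -> float:
        ix = max(0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        union = self.w * self.h + other.w * other.h - inter
        return inter / union if union else 0.0


def lbp_code(patch: np.ndarray, cfg: LBPConfig = LBPConfig()) -> int:
    """LBP code of the center pixel of a 3x3 patch; ties (z = 0) count as 1."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3x3 patch, got {patch.shape}")
    center = patch[1, 1]
    code = 0
    for k, (dy, dx) in enumerate(_NEIGHBOURS):
        if patch[1 + dy, 1 + dx] - center >= 0:
            code |= 1 << k
    return code


def lbp_code_map(image: np.ndarray) -> np.ndarray:
    """LBP codes for all interior pixels (vectorized; border excluded)."""
    img = np.asarray(image, dtype=np.int32)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    c = img[1:-1, 1:-1]
    codes = np.zeros_like(c)
    for k, (dy, dx) in enumerate(_NEIGHBOURS):
        nb = img[1 + dy:img.shape[0] - 1 + dy, 1 + dx:img.shape[1] - 1 + dx]
        codes |= ((nb - c) >= 0).astype(np.int32) << k
    return codes


def lbp_histogram(image: np.ndarray, window: DetectionWindow,
                  cfg: LBPConfig = LBPConfig()) -> np.ndarray:
    """L1-normalized 256-bin histogram of LBP codes inside a window.

    Pixels whose 3x3 neighbourhood leaves the image are skipped rather than
    padded, so windows touching the border simply use fewer pixels.
    """
    img = np.asarray(image, dtype=float)
    y0, y1 = max(window.y, 0), min(window.y + window.h, img.shape[0])
    x0, x1 = max(window.x, 0), min(window.x + window.w, img.shape[1])
    if y1 - y0 < 3 or x1 - x0 < 3:
        raise ValueError("window must cover at least 3x3 pixels inside the image")
    codes = lbp_code_map(img[y0:y1, x0:x1])
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def strong_classify(features: np.ndarray, clf: StrongClassifier) -> int:
    """Boosted majority vote: 1 iff the weighted votes reach half the weight."""
    weights = np.array([np.log(1.0 / w.beta) for w in clf.weak])
    votes = np.array([w.vote(features) for w in clf.weak], dtype=float)
    return int(votes @ weights >= 0.5 * weights.sum())


_EPS_CLAMP = 1e-10


def train_adaboost(samples: np.ndarray, labels: np.ndarray,
                   n_rounds: int = 10) -> StrongClassifier:
    """Discrete AdaBoost over decision stumps on histogram bins.

    Each round picks the (bin, threshold, polarity) stump with minimum
    weighted error eps, sets beta = eps / (1 - eps), multiplies the weights
    of correctly classified samples by beta and renormalizes.  eps is
    clamped away from 0 and 1/2 to keep beta inside (0, 1).
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("samples must be (n, d) aligned with labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes present")
    n, d = X.shape
    w = np.full(n, 1.0 / n)
    weak: list[WeakClassifier] = []
    for _ in range(n_rounds):
        eps, j, thr, pol = _best_stump(X, y, w)
        eps = min(max(eps, _EPS_CLAMP), 0.5 - _EPS_CLAMP)
        beta = eps / (1.0 - eps)
        stump = WeakClassifier(j, thr, pol, beta)
        weak.append(stump)
        pred = np.array([stump.vote(X[i]) for i in range(n)])
        w = np.where(pred == y, w * beta, w)
        w /= w.sum()
    return StrongClassifier(tuple(weak))


def _best_stump(X: np.ndarray, y: np.ndarray,
                w: np.ndarray) -> tuple[float, int, float, int]:
    """Minimum-weighted-error stump via a sorted cumulative-weight sweep.

    For a threshold between sorted positions i and i+1 of one feature, the
    polarity +1 error is (weight of positives at or below) + (weight of
    negatives above); the polarity -1 error is its complement since the
    weights sum to 1.
    """
    wy1 = w * (y == 1)
    wy0 = w * (y == 0)
    tot0 = wy0.sum()
    total = w.sum()
    best = (np.inf, 0, 0.0, 1)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        cs1 = np.cumsum(wy1[order])
        cs0 = np.cumsum(wy0[order])
        cs = col[order]
        valid = np.nonzero(cs[:-1] < cs[1:])[0]
        if valid.size == 0:
            continue
        err_pos = cs1[valid] + (tot0 - cs0[valid])
        err_neg = total - err_pos
        i_pos = int(np.argmin(err_pos))
        i_neg = int(np.argmin(err_neg))
        for err, i, pol in ((float(err_pos[i_pos]), i_pos, 1),
                            (float(err_neg[i_neg]), i_neg, -1)):
            if err < best[0]:
                k = valid[i]
                best = (err, j, float((cs[k] + cs[k + 1]) / 2.0), pol)
    return best


def train_cascade(samples: np.ndarray, labels: np.ndarray,
                  n_stages: int = 3, rounds_per_stage: int = 5) -> Cascade:
    """Train a rejection cascade; each stage sees only survivors of the last.

    Negatives accepted by earlier stages are the hard examples for the next
    stage; training stops early if no negatives survive.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels, dtype=int)
    stages: list[StrongClassifier] = []
    keep = np.ones(len(y), dtype=bool)
    for _ in range(n_stages):
        if len(np.unique(y[keep])) < 2:
            break
        stage = train_adaboost(X[keep], y[keep], rounds_per_stage)
        stages.append(stage)
        pred = np.array([strong_classify(X[i], stage) for i in range(len(y))])
        keep &= (pred == 1)  # positives and false positives continue
    if not stages:
        raise ValueError("could not train any cascade stage")
    return Cascade(tuple(stages))


def sliding_window_detect(image: np.ndarray, clf: StrongClassifier | Cascade,
                          window_size: tuple[int, int] = (96, 160),
                          step: int = 16,
                          scales: tuple[float, ...] = (1.0,)) -> list[DetectionWindow]:
    """Scan the image at each scale and stride; return positive windows.

    Windows are visited coarse-to-fine in scale and row-major within a
    scale, so the output order is deterministic.  Window coordinates are
    always in the original image frame.
    """
    img = np.asarray(image, dtype=float)
    wins: list[DetectionWindow] = []
    classify = clf.classify if isinstance(clf, Cascade) else (
        lambda f: strong_classify(f, clf))
    any_scale_fits = False
    for scale in sorted(scales, reverse=True):
        ww = int(round(window_size[0] / scale))
        wh = int(round(window_size[1] / scale))
        if ww > img.shape[1] or wh > img.shape[0] or ww < 3 or wh < 3:
            continue
        any_scale_fits = True
        for y in range(0, img.shape[0] - wh + 1, step):
            for x in range(0, img.shape[1] - ww + 1, step):
                win = DetectionWindow(x, y, ww, wh)
                if classify(lbp_histogram(img, win)) == 1:
                    wins.append(win)
    if not any_scale_fits:
        warnings.warn("image smaller than the minimum detection window")
    return wins


def crop_body(image: np.ndarray,
              detections: list[DetectionWindow]) -> tuple[np.ndarray, DetectionWindow]:
    """Crop the union bounding box of the positive detections."""
    img = np.asarray(image)
    pos = [d for d in detections if d.label == "positive"]
    if not pos:
        raise CropFailedError(
            "no torso detected; pass an explicit crop region instead")
    x0 = max(0, min(d.x for d in pos))
    y0 = max(0, min(d.y for d in pos))
    x1 = min(img.shape[1], max(d.x + d.w for d in pos))
    y1 = min(img.shape[0], max(d.y + d.h for d in pos))
    box = DetectionWindow(x0, y0, x1 - x0, y1 - y0)
    return img[y0:y1, x0:x1].copy(), box


# ---------------------------------------------------------------------------
# classifier serialization

def save_classifier(clf: StrongClassifier | Cascade, path) -> None:
    if isinstance(clf, Cascade):
        obj = {"kind": "cascade", "stages": [_stage_dict(s) for s in clf.stages]}
    else:
        obj = {"kind": "strong", **_stage_dict(clf)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)


def load_classifier(path) -> StrongClassifier | Cascade:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("kind") == "cascade":
        return Cascade(tuple(_stage_from(s) for s in obj["stages"]))
    return _stage_from(obj)


def _stage_dict(s: StrongClassifier) -> dict:
    return {"weak": [{"feature_index": w.feature_index, "threshold": w.threshold,
                      "polarity": w.polarity, "beta": w.beta} for w in s.weak]}


def _stage_from(d: dict) -> StrongClassifier:
    return StrongClassifier(tuple(
        WeakClassifier(w["feature_index"], w["threshold"], w["polarity"], w["beta"])
        for w in d["weak"]))
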