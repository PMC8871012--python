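"""Synthetic spine phantoms with analytically known Cobb angle.

A phantom is a stack of vertebra boxes whose centers follow a single-arch
sinusoidal centerline x(y) = A * sin(pi * (y - y0) / L) inside the arch and a
straight vertical line outside it.  Each box is rotated so its endplates stay
perpendicular to the local centerline tangent, which makes the true Cobb
angle an analytic quantity: the spread of tangent angles over the vertebral
centers inside the arch.  Phantoms therefore let every stage of the
measurement chain — outlier rejection, imputation, apex and end-vertebra
selection — be tested without any patient data.

Corner noise is i.i.d. Gaussian (default sigma 1 px), a minimal stand-in for
landmark-detection jitter.  All randomness is driven by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Point2D, SpineSequence, VertebraBox, _box_from_pose

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "true_cobb",
           "amplitude_for_cobb", "render_image"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of a synthetic spine.

    The defaults draw a 17-vertebra spine on a 512 x 1024 canvas with the
    arch spanning the whole stack, vertebra size tapering from 90 px wide at
    the top to 120 px at the bottom (thoracic vertebrae are smaller than
    lumbar ones), and detection scores uniform in [0.6, 1.0].
    """

    n_vertebrae: int = 17
    amplitude: float = 60.0          # lateral arch amplitude, px
    arch_top: float = 100.0          # y of the arch start, px
    arch_len: float = 820.0          # arch extent in y, px
    vertebra_width: tuple[float, float] = (90.0, 120.0)  # top → bottom taper
    vertebra_height: tuple[float, float] = (30.0, 45.0)
    corner_noise_sigma: float = 0.0  # px
    score_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0
    image_width: int = 512
    image_height: int = 1024
    center_x: float = 256.0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 5:
            raise ValueError("need at least 5 vertebrae")
        if self.arch_len <= 0:
            raise ValueError("arch_len must be positive")
        if self.corner_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.arch_top < 0 or self.arch_top + self.arch_len > self.image_height:
            raise ValueError("arch extends outside the image")


@dataclass(frozen=True)
class Phantom:
    seq: SpineSequence
    true_cobb_deg: float
    true_apex_index: int
    config: PhantomConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _center_ys(cfg: PhantomConfig) -> np.ndarray:
    """Vertebra center y positions, equally spaced through the arch."""
    step = cfg.arch_len / cfg.n_vertebrae
    return cfg.arch_top + step * (np.arange(cfg.n_vertebrae) + 0.5)


def _centerline_x(cfg: PhantomConfig, y: np.ndarray) -> np.ndarray:
    inside = (y >= cfg.arch_top) & (y <= cfg.arch_top + cfg.arch_len)
    phase = np.pi * (y - cfg.arch_top) / cfg.arch_len
    return cfg.center_x + np.where(inside, cfg.amplitude * np.sin(phase), 0.0)


def _tangent_deg(cfg: PhantomConfig, y: np.ndarray) -> np.ndarray:
    """Centerline tangent angle theta(y) = atan(dx/dy), degrees."""
    inside = (y >= cfg.arch_top) & (y <= cfg.arch_top + cfg.arch_len)
    phase = np.pi * (y - cfg.arch_top) / cfg.arch_len
    slope = np.where(inside, cfg.amplitude * np.pi / cfg.arch_len * np.cos(phase), 0.0)
    return np.degrees(np.arctan(slope))


def true_cobb(cfg: PhantomConfig) -> float:
    """Analytic Cobb angle: tangent-angle spread over the vertebral centers."""
    theta = _tangent_deg(cfg, _center_ys(cfg))
    return float(theta.max() - theta.min())


def amplitude_for_cobb(target_deg: float, cfg: PhantomConfig | None = None,
                       tol_deg: float = 0.1) -> float:
    """Invert true_cobb for the arch amplitude by bisection.

    Finds A such that the phantom built from ``cfg`` with that amplitude has
    an analytic Cobb angle within ``tol_deg`` of ``target_deg``.
    """
    if cfg is None:
        cfg = PhantomConfig()
    if target_deg < 0:
        raise ValueError("target angle must be non-negative")
    if target_deg == 0:
        return 0.0
    lo, hi = 0.0, 1.0

    def f(a: float) -> float:
        return true_cobb(_with(cfg, amplitude=a))

    while f(hi) < target_deg:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"cannot reach {target_deg} degrees")
    while f(hi) - f(lo) > tol_deg / 4:
        mid = (lo + hi) / 2.0
        if f(mid) < target_deg:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _with(cfg: PhantomConfig, **kw) -> PhantomConfig:
    from dataclasses import replace
    return replace(cfg, **kw)


def generate_phantom(cfg: PhantomConfig) -> Phantom:
    """Build a scored vertebra-box sequence from the analytic centerline."""
    rng = np.random.default_rng(cfg.seed)
    ys = _center_ys(cfg)
    xs = _centerline_x(cfg, ys)
    theta = _tangent_deg(cfg, ys)
    n = cfg.n_vertebrae
    frac = np.linspace(0.0, 1.0, n)
    widths = cfg.vertebra_width[0] + frac * (cfg.vertebra_width[1] - cfg.vertebra_width[0])
    heights = cfg.vertebra_height[0] + frac * (cfg.vertebra_height[1] - cfg.vertebra_height[0])
    scores = rng.uniform(cfg.score_range[0], cfg.score_range[1], size=n)

    boxes = []
    for i in range(n):
        # endplates perpendicular to the tangent: with y down, a rightward
        # lean (dx/dy > 0) tips the endplate's right corner upward
        box = _box_from_pose(float(xs[i]), float(ys[i]), float(widths[i]),
                             float(heights[i]), float(-theta[i]), float(scores[i]))
        if cfg.corner_noise_sigma > 0:
            jitter = rng.normal(0.0, cfg.corner_noise_sigma, size=(4, 2))
            tl, tr, bl, br = box.corners()
            pts = [Point2D(p.x + jitter[k, 0], p.y + jitter[k, 1])
                   for k, p in enumerate((tl, tr, bl, br))]
            box = VertebraBox(pts[0], pts[1], pts[2], pts[3],
                              score=float(scores[i]), imputed=False)
        else:
            box = VertebraBox(box.top_left, box.top_right, box.bottom_left,
                              box.bottom_right, score=float(scores[i]), imputed=False)
        boxes.append(box)

    seq = SpineSequence(tuple(boxes), cfg.image_width, cfg.image_height)
    theta_clean = _tangent_deg(cfg, ys)
    apex = int(np.argmax(np.abs(_centerline_x(cfg, ys) - cfg.center_x)))
    return Phantom(seq=seq, true_cobb_deg=float(theta_clean.max() - theta_clean.min()),
                   true_apex_index=apex, config=cfg)


def render_image(ph: Phantom, w: int | None = None, h: int | None = None,
                 contrast: float = 1.0, noise: float = 0.0,
                 seed: int | None = None) -> np.ndarray:
    """Rasterize a phantom into an 8-bit pseudo-radiograph.

    Bright filled vertebra quadrilaterals on a torso-shaped mid-gray band
    over a dark background, with optional additive Gaussian noise.  Used to
    exercise the body-cropping stage; it makes no attempt at radiographic
    realism (no ribs, pelvis or beam profile).
    """
    from skimage.draw import polygon

    cfg = ph.config if ph.config is not None else PhantomConfig()
    w = w if w is not None else cfg.image_width
    h = h if h is not None else cfg.image_height
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    img = np.full((h, w), 40.0)
    # torso band: centered on the spine, wide enough to cover the arch
    half = min(w // 2 - 1, int(cfg.amplitude + 4 * cfg.vertebra_width[1]))
    x0 = max(0, int(cfg.center_x) - half)
    x1 = min(w, int(cfg.center_x) + half)
    y0 = max(0, int(cfg.arch_top) - 30)
    y1 = min(h, int(cfg.arch_top + cfg.arch_len) + 30)
    img[y0:y1, x0:x1] = 110.0

    level = 110.0 + 100.0 * contrast
    for box in ph.seq.boxes:
        tl, tr, bl, br = box.corners()
        rr, cc = polygon([tl.y, tr.y, br.y, bl.y], [tl.x, tr.x, br.x, bl.x],
                         shape=img.shape)
        img[rr, cc] = level

    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
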