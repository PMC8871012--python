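import numpy as np
import pytest

from cobbmeter.geometry import Point2D, SpineSequence, VertebraBox
from cobbmeter.synthetic import (PhantomConfig, amplitude_for_cobb,
                                 generate_phantom)


@pytest.fixture(scope="session")
def fixture_records():
    from cobbmeter.evaluation import load_fixture_records

    return load_fixture_records()


@pytest.fixture(scope="session")
def phantom_40():
    """Noise-free 17-vertebra phantom with a 40-degree analytic Cobb angle."""
    cfg = PhantomConfig(amplitude=amplitude_for_cobb(40.0), seed=11)
    return generate_phantom(cfg)


def make_phantom(cobb_deg, noise=0.0, seed=0, **kw):
    base = PhantomConfig(corner_noise_sigma=noise, seed=seed, **kw)
    cfg = PhantomConfig(amplitude=amplitude_for_cobb(cobb_deg, base),
                        corner_noise_sigma=noise, seed=seed, **kw)
    return generate_phantom(cfg)


def straight_sequence(n=17, x=256.0, width=90.0, height=30.0, spacing=50.0,
                      scores=None):
    """Vertical stack of axis-aligned boxes (a perfectly straight spine)."""
    boxes = []
    for i in range(n):
        cy = 100.0 + i * spacing
        s = 1.0 if scores is None else scores[i]
        boxes.append(axis_box(x, cy, width, height, score=s))
    return SpineSequence(tuple(boxes))


def axis_box(cx, cy, w, h, score=1.0):
    hw, hh = w / 2.0, h / 2.0
    return VertebraBox(
        Point2D(cx - hw, cy - hh), Point2D(cx + hw, cy - hh),
        Point2D(cx - hw, cy + hh), Point2D(cx + hw, cy + hh), score=score)


def shift_box(box, dx, dy=0.0):
    pts = [Point2D(p.x + dx, p.y + dy) for p in box.corners()]
    return VertebraBox(*pts, score=box.score)


def mirror_sequence(seq):
    """Reflect left-right about the image midline; corner roles swap sides."""
    w = seq.image_width
    boxes = []
    for b in seq.boxes:
        def m(p):
            return Point2D(w - p.x, p.y)
        boxes.append(VertebraBox(m(b.top_right), m(b.top_left),
                                 m(b.bottom_right), m(b.bottom_left),
                                 score=b.score))
    return SpineSequence(tuple(boxes), w, seq.image_height)


def transform_sequence(seq, fn):
    boxes = [VertebraBox(*[fn(p) for p in b.corners()], score=b.score)
             for b in seq.boxes]
    boxes.sort(key=lambda b: b.center.y)
    return SpineSequence(tuple(boxes), seq.image_width, seq.image_height)
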