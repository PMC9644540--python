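import math

import numpy as np
import pytest

from cromkit.assembly import order_regions, pair_scenes
from cromkit.phantom import PhantomParams, generate_phantom
from cromkit.regions import PoseScene, VertebraRegion


def rect_region(x0, y0, w, h, seg_class="c3toc7", label=None, step=2.0):
    """Axis-aligned rectangular region with a densified outline."""
    xs = np.arange(x0, x0 + w, step)
    ys = np.arange(y0, y0 + h, step)
    top = np.column_stack([xs, np.full_like(xs, y0)])
    right = np.column_stack([np.full_like(ys, x0 + w), ys])
    bot = np.column_stack([xs[::-1] + step, np.full_like(xs, y0 + h)])
    left = np.column_stack([np.full_like(ys, x0), ys[::-1] + step])
    contour = np.vstack([top, right, bot, left])
    return VertebraRegion(seg_class=seg_class, contour=contour, label=label)


def rotate_scene(scene: PoseScene, deg: float) -> PoseScene:
    """Rigidly rotate every contour about the image center."""
    c = np.array(scene.image_size) / 2.0
    r = math.radians(deg)
    rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
    regs = [
        VertebraRegion(rg.seg_class, (rg.contour - c) @ rot.T + c, rg.label)
        for rg in scene.regions
    ]
    return PoseScene(scene.pose, scene.image_size, regs)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default noise-free phantom pair with truth."""
    return generate_phantom(PhantomParams())


@pytest.fixture(scope="session")
def clean_pair(clean_phantom):
    flex, ext, truth = clean_phantom
    pair = pair_scenes(order_regions(flex), order_regions(ext))
    return pair, truth
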