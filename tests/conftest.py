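import numpy as np
import pytest

from mesobrush import fixtures as fx
from mesobrush.geometry import Circle, Rect
from mesobrush.ingredients import FiberSpec, MembraneBinding, ingredient_from_image
from mesobrush.physics import Fixture, World, WorldConfig
from mesobrush.scene import Scene


@pytest.fixture
def unit_circle_contour():
    return fx.ellipse_contour(1.0, 1.0, n=64)


@pytest.fixture
def ellipse_4_1():
    return fx.ellipse_contour(4.0, 1.0, n=64)


@pytest.fixture
def demo_palette():
    return fx.demo_ingredients(seed=0)


@pytest.fixture
def scene_with_palette(demo_palette):
    scene = Scene(canvas=(400.0, 400.0), config=WorldConfig(rng_seed=7))
    for ing in demo_palette.values():
        scene.add_ingredient(ing)
    return scene


def make_circle_body(world: World, pos, r=2.0, name="c", **kw):
    return world.add_body(name, pos,
                          fixtures=[Fixture(Circle((0.0, 0.0), r), "protein")],
                          **kw)


def make_rect_body(world: World, pos, w=10.0, h=4.0, name="r", **kw):
    return world.add_body(name, pos,
                          fixtures=[Fixture(Rect((0.0, 0.0), w, h), "protein")],
                          **kw)


@pytest.fixture
def simple_world():
    return World(WorldConfig(rng_seed=3))
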