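import numpy as np
import pytest

import graphophon as gp


@pytest.fixture(scope="session")
def ref_table() -> gp.PhoneticDistanceTable:
    return gp.reference_distance_table()


@pytest.fixture
def plus_sign() -> gp.GlyphRaster:
    grid = np.zeros((3, 3))
    grid[1, :] = 1
    grid[:, 1] = 1
    return gp.GlyphRaster("plus", grid)


@pytest.fixture
def filled_square() -> gp.GlyphRaster:
    return gp.GlyphRaster("square", np.ones((5, 5)))


@pytest.fixture(scope="session")
def planted_pixel(ref_table):
    """A library with a planted pixel-count-systematic material (shared:
    construction is the expensive part)."""
    return gp.plant_material_library(
        ref_table.pairs, ref_table.distances(), "pixel", gp.PlantConfig(seed=11)
    )


@pytest.fixture(scope="session")
def small_library() -> gp.GlyphLibrary:
    return gp.generate_glyph_library(gp.GlyphGenConfig(n_glyphs=24, seed=3))
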