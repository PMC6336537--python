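"""Shared fixtures: small libraries, rendered units and screen simulations.

Everything is generated programmatically and seeded; the heavier default
library descriptor table is session-scoped so acceptance tests share it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import toposcreen as ts
from toposcreen.library import Primitive, TopoUnitDesign


@pytest.fixture(scope="session")
def small_library():
    return ts.generate_library(30, seed=11)


@pytest.fixture(scope="session")
def small_descriptors(small_library):
    return ts.library_descriptors(small_library, seed=11)


@pytest.fixture()
def circle_design():
    return TopoUnitDesign("circle100", (Primitive("circle", 100.0, 150.0, 150.0),))


@pytest.fixture()
def flat_design():
    return TopoUnitDesign("flat", ())


@pytest.fixture(scope="session")
def rendered_unit():
    """One simulated unit rendered noise-free, with its planted cell table."""
    model = ts.default_planted_model()
    cells = ts.simulate_unit({"fcp": 0.3, "circ_diam": 20.0}, model, seed=5)
    mask = ts.rasterize(TopoUnitDesign("u", (Primitive("circle", 40.0, 150.0, 150.0),)))
    stack = ts.render_unit(cells, mask, noise_sd=0.0, seed=5)
    return cells, stack


@pytest.fixture(scope="session")
def mini_screen():
    """A 100-design screen in table mode: descriptors, cells, truth, units."""
    library = ts.generate_library(100, seed=3)
    descriptors = ts.library_descriptors(library, seed=3)
    layout = ts.layout_chip(library, rows=16, cols=16, seed=3, offset=(8, 8))
    model = ts.default_planted_model()
    cells, truth = ts.simulate_screen(library, layout, model, seed=3,
                                      descriptors=descriptors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        units = ts.summarize_units(ts.classify_tgm1(cells))
    return {
        "library": library,
        "descriptors": descriptors,
        "layout": layout,
        "model": model,
        "cells": cells,
        "truth": truth,
        "units": units,
    }
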