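import numpy as np
import pytest

from lnclonal import (
    MarkedPointPattern,
    make_elliptical_domain,
    rectangle_domain,
    simulate_csr_pattern,
)


@pytest.fixture
def unit_square():
    return rectangle_domain(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def ellipse():
    return make_elliptical_domain(500.0, 300.0, 64)


@pytest.fixture
def line_pattern():
    """Five collinear points at x = 0..4, colors A,B,A,B,A."""
    dom = rectangle_domain(-1.0, -1.0, 5.0, 1.0)
    xy = np.column_stack([np.arange(5.0), np.zeros(5)])
    return MarkedPointPattern(xy, np.array(list("ABABA"), dtype=object), dom)


@pytest.fixture
def monochrome_pattern():
    dom = rectangle_domain(-1.0, -1.0, 5.0, 1.0)
    xy = np.column_stack([np.arange(5.0), np.zeros(5)])
    return MarkedPointPattern(xy, np.array(["A"] * 5, dtype=object), dom)


@pytest.fixture
def csr_equal4(unit_square):
    """Equal-4-color CSR with 1000 points per color in the unit square."""
    return simulate_csr_pattern(
        unit_square, {c: 1000 for c in "ABCD"}, seed=424242
    )


@pytest.fixture
def corner_square_pattern(unit_square):
    """Four points at the unit-square corners: left column A, right column B."""
    xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    marks = np.array(["A", "B", "A", "B"], dtype=object)
    return MarkedPointPattern(xy, marks, unit_square)
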