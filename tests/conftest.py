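"""Shared fixtures: small synthetic systems with known ground truth."""

import numpy as np
import pytest

from strandscan import (
    BackboneFrame,
    SheetSpec,
    SystemTopology,
    build_bb_matrix,
    build_p_matrix,
    build_shift_library,
    make_ideal_sheet,
)


@pytest.fixture(scope="session")
def parallel_sheet_12x32():
    """Ideal flat 12-strand parallel in-register sheet, SL=32."""
    return make_ideal_sheet(SheetSpec(n_strands=12, strand_length=32))


@pytest.fixture(scope="session")
def small_sheet_3x10():
    """Ideal 3-strand parallel in-register sheet, SL=10."""
    return make_ideal_sheet(SheetSpec(n_strands=3, strand_length=10))


@pytest.fixture()
def analyzed_sheet(parallel_sheet_12x32):
    """(frame, topology, bb, p) for the 12x32 parallel sheet."""
    frame, topology, _ = parallel_sheet_12x32
    bb = build_bb_matrix(frame, topology)
    p = build_p_matrix(bb, build_shift_library(topology.strand_length))
    return frame, topology, bb, p


def two_strand_frame(separation=4.8, SL=6, rise=3.4):
    """Two straight parallel in-register strands a given distance apart."""
    coords = np.zeros((2 * SL, 3))
    coords[:SL, 0] = np.arange(SL) * rise
    coords[SL:, 0] = np.arange(SL) * rise
    coords[SL:, 1] = separation
    return BackboneFrame(coords), SystemTopology.regular(2, SL)
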