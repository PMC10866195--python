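"""Shared fixtures: miniature designs keep unit tests fast."""

import pytest

import stprf
from stprf.design import BarGeometry, TemporalCondition


@pytest.fixture(scope="session")
def mini_geometry():
    """A small 3-step, 2-angle bar design on a 31 px grid (tiles 24 deg)."""
    return BarGeometry(bar_width_deg=10.0, overlap_deg=3.0, n_steps=3,
                       angles_deg=(0.0, 90.0), grid_px=31)


@pytest.fixture(scope="session")
def mini_conditions():
    """Two 1 s temporal conditions: flicker and continuous."""
    return {
        1: TemporalCondition(1, on_ms=100.0, isi_ms=100.0, n_images=5,
                             slot_ms=1000.0),
        2: TemporalCondition(2, on_ms=1000.0, isi_ms=0.0, n_images=1,
                             slot_ms=1000.0),
        3: TemporalCondition(3, on_ms=300.0, isi_ms=200.0, n_images=2,
                             slot_ms=1000.0),
    }


@pytest.fixture(scope="session")
def mini_seq(mini_geometry, mini_conditions):
    """Two runs of the miniature design (1200 frames total)."""
    schedules = stprf.counterbalanced_schedules(mini_geometry, n_runs=2,
                                                seed=1)
    from stprf.design import _assemble

    return _assemble(mini_geometry, schedules, mini_conditions, 10.0, "mini")


@pytest.fixture(scope="session")
def spatio_seq2():
    """Two full-size spatiotemporal runs (for model/engine equivalence)."""
    return stprf.spatiotemporal_sequence(n_runs=2, seed=0)


@pytest.fixture(scope="session")
def default_hrf_kernel():
    return stprf.default_hrf()
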