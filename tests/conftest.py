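"""Shared fixtures: rendered reference frames and the raft-ordering study.

Everything is generated at test time from the synthetic module; expensive
fixtures are session-scoped so tracing-accuracy and acceptance checks share
one render/simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from guvshape import ordering as od
from guvshape import synthetic as syn
from guvshape import tracing as tr

PIXEL_UM = 0.1
FRAME_PX = 512
RADIUS_UM = 10.0


@pytest.fixture(scope="session")
def circle_frame() -> syn.ImageFrame:
    """Noiseless circular GUV slice: R = 10 um at 0.1 um/px in a 512 px frame."""
    shape = syn.make_contour(RADIUS_UM, frame_size_px=FRAME_PX, pixel_size_um=PIXEL_UM)
    return syn.render_guv_slice(shape, syn.OpticsModel(), size_px=FRAME_PX)


@pytest.fixture(scope="session")
def traced_circle(circle_frame):
    trace, circle, profile = tr.trace_guv(circle_frame.pixels)
    return trace, circle, profile


def _ordering_protocol(seed: int) -> tuple[float, float]:
    """One seed of the ordering study: equilibrated squares vs rods obtained
    by in-place transformation (with brief post-transform relaxation)."""
    squares = od.init_config(200, od.SDR_DIMS_NM, coverage=0.23, seed=seed)
    eq = od.run_mc(squares, od.MoveSettings(sweeps=10_000, seed=seed + 100)).final
    report = od.transform_shapes(
        eq, od.EDR_DIMS_NM, n_substeps=20,
        relax=od.MoveSettings(sweeps=50, seed=seed + 200), max_retries=300,
    )
    rods = od.run_mc(report.config, od.MoveSettings(sweeps=2000, seed=seed + 300)).final
    return od.order_metrics(eq).ordered_fraction, od.order_metrics(rods).ordered_fraction


@pytest.fixture(scope="session")
def ordering_study():
    """Ordered fractions (squares, transformed rods) over five seeds."""
    results = [_ordering_protocol(seed) for seed in range(1, 6)]
    arr = np.asarray(results)
    return {"squares": arr[:, 0], "transformed": arr[:, 1]}
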