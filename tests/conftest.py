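import numpy as np
import pytest

from microflow.model import (
    Clip, FieldOfView, FlowScore, QualityFlags, VesselSegment,
)


def make_vessel(vessel_id, points, diameter_um=10.0, flow=3):
    return VesselSegment(
        vessel_id=vessel_id,
        centerline=np.asarray(points, dtype=float),
        diameter_um=diameter_um,
        flow=FlowScore(flow),
    )


def make_clip(vessels, width=1000.0, height=1000.0, clip_id="c0",
              subject_id="S0", time_point=6, duration=5.0,
              quality=None):
    return Clip(
        clip_id=clip_id, subject_id=subject_id, time_point_h=time_point,
        fov=FieldOfView(width, height), vessels=tuple(vessels),
        duration_s=duration, quality=quality or QualityFlags(),
    )


@pytest.fixture
def square_fov():
    return FieldOfView(1000.0, 1000.0)


@pytest.fixture
def five_vessel_clip():
    """Hand-computed fixture in a 1 mm² FOV.

    Small vessels: v1 horizontal y=100 spanning (flow 3, in-view 1000 μm,
    3 grid crossings), v2 vertical x=100 spanning (flow 1, 1000 μm, 3
    crossings), v3 main diagonal (flow 2, 1000√2 μm, 6 crossings), v5
    (600,600)->(900,600) (flow 0, 300 μm, 1 crossing).  v4 is a medium
    vessel (30 μm) that must not affect any metric.

    Expected: TVD = (2300 + 1000√2)/1000, PPV = (1000 + 1000√2)/(2300 +
    1000√2), De Backer = 13/6, quadrant modes (TL,TR,BL,BR) = (2,3,1,2),
    MFI = 2.0, HI = (3-1)/2 = 1.0.
    """
    return make_clip([
        make_vessel("v1", [(-100, 100), (1100, 100)], 10.0, 3),
        make_vessel("v2", [(100, 0), (100, 1000)], 15.0, 1),
        make_vessel("v3", [(0, 0), (1000, 1000)], 5.0, 2),
        make_vessel("v4", [(-50, 900), (1050, 900)], 30.0, 3),
        make_vessel("v5", [(600, 600), (900, 600)], 8.0, 0),
    ])


FIVE_VESSEL_EXPECTED = {
    "tvd_mm_per_mm2": (2300.0 + 1000.0 * np.sqrt(2)) / 1000.0,
    "ppv_fraction": (1000.0 + 1000.0 * np.sqrt(2))
    / (2300.0 + 1000.0 * np.sqrt(2)),
    "de_backer_n_per_mm": 13.0 / 6.0,
    "mfi": 2.0,
    "heterogeneity_index": 1.0,
}
FIVE_VESSEL_EXPECTED["pvd_mm_per_mm2"] = (
    FIVE_VESSEL_EXPECTED["ppv_fraction"] * FIVE_VESSEL_EXPECTED["tvd_mm_per_mm2"]
)
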