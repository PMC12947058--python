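import numpy as np
import pytest

import filmdose as fd
from filmdose.reference import ANCHOR_VX_LG, ANCHOR_VX_SM


@pytest.fixture(scope="session")
def vxsm_model():
    """Gamma single-event model calibrated at the small-voxel 0.003 Gy anchor."""
    return fd.calibrate_from_anchor(ANCHOR_VX_SM)


@pytest.fixture(scope="session")
def vxlg_model():
    """Gamma single-event model calibrated at the large-voxel 0.003 Gy anchor."""
    return fd.calibrate_from_anchor(ANCHOR_VX_LG)


@pytest.fixture(scope="session")
def anchor_field_1e6(vxsm_model):
    """10^6-voxel sampled field at the anchor dose (0.003 Gy, vx-sm)."""
    return fd.sample_field(vxsm_model, fd.VX_SM, 0.003, (100, 100, 100), seed=1234)


@pytest.fixture(scope="session")
def vxlg_histograms(vxlg_model):
    """Per-dose f(z; D) histograms at the 15 delivered doses (vx-lg engine)."""
    from filmdose.reference import DOSES_DELIVERED

    hists = []
    for k, d in enumerate(DOSES_DELIVERED):
        f = fd.sample_field(vxlg_model, fd.VX_LG, d, (20000, 1, 1), seed=100 + k)
        hists.append(fd.histogram_f(f))
    return hists
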