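"""Reference study conditions for 6-MV irradiated EBT3 film.

Published summary values for the two scoring-voxel presets and the two
readout modalities, used as generator defaults and as calibration anchors
throughout the package.  Spreads are stored as fractions (3.43 = 343%).
"""
from .engine import CalibrationAnchor

#: Delivered dose series (Gy), 0.003-0.5 Gy, as irradiated.
DOSES_DELIVERED = (
    0.003, 0.005, 0.007, 0.01, 0.02, 0.03, 0.04, 0.05,
    0.07, 0.09, 0.1, 0.2, 0.3, 0.4, 0.5,
)

#: Dose column of the published voxel-statistics table.  It differs from
#: the delivered list in its second to fourth entries (0.006/0.009/0.011
#: vs 0.005/0.007/0.01); the discrepancy is unexplained at the source, so
#: both lists are provided and any dose list is accepted downstream.
DOSES_TABULATED = (
    0.003, 0.006, 0.009, 0.011, 0.02, 0.03, 0.04, 0.05,
    0.07, 0.09, 0.1, 0.2, 0.3, 0.4, 0.5,
)

#: 0.003 Gy anchor for the Raman-sampling-volume voxels (f_z=0, spread).
ANCHOR_VX_SM = CalibrationAnchor(dose=0.003, zero_fraction=0.65, spread=3.43)

#: 0.003 Gy anchor for the monomer-crystal-sized voxels.
ANCHOR_VX_LG = CalibrationAnchor(dose=0.003, zero_fraction=0.35, spread=2.05)

#: Reported one-hit fit parameters (m, alpha [1/Gy], C) per modality.
OD_FIT_PARAMS = (0.19, 1.2, 0.026)
RS_FIT_PARAMS = (8.6, 1.02, 1.96)

#: Published relative SD of specific energy (%) by dose, small voxels.
SPREAD_PCT_VX_SM = dict(zip(DOSES_TABULATED, (
    343, 237, 189, 167, 132, 108, 95, 88, 74, 63, 55, 41, 35, 33, 27)))
#: Same for the large voxels.
SPREAD_PCT_VX_LG = dict(zip(DOSES_TABULATED, (
    205, 138, 131, 114, 78, 63, 55, 46, 43, 39, 36, 25, 20, 17, 15)))
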