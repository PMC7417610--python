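"""Reference measurements bundled for worked examples and checks.

Published leaf and epidermal-cell dimensions of the maize fourth leaf at
three days after emergence, for two gibberellin-contrast pairs: the
GA-deficient *dwarf3* mutant against its W23xL317 wild type, and the
GA-overproducing UBI::GA20OX-1 line against its B104 wild type.  Means are
given with standard errors; ``percent_reported`` is the tabulated percent
difference of the treatment relative to its wild type.

Note: three ``percent_reported`` entries (marked ``consistent = False``)
cannot be reproduced from the rounded means printed alongside them under any
integer rounding rule; they were evidently derived from unrounded underlying
data.  The remaining fifteen agree exactly with
:func:`anisokin.kinematics.percent_difference`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["leaf_dimensions_reference"]

_ROWS = [
    # pair, trait, unit, control, ctrl_mean, ctrl_se, treatment, trt_mean, trt_se, pct, consistent
    ("dwarf3", "leaf_length", "mm", "W23xL317", 353, 10, "dwarf3", 141, 10, -60, True),
    ("dwarf3", "cell_length", "um", "W23xL317", 147, 3, "dwarf3", 152, 3, 3, True),
    ("dwarf3", "leaf_width", "mm", "W23xL317", 23.3, 1.0, "dwarf3", 24.2, 0.9, 4, True),
    ("dwarf3", "cell_width", "um", "W23xL317", 24.4, 1.2, "dwarf3", 29.4, 0.7, 21, False),
    ("dwarf3", "leaf_thickness", "um", "W23xL317", 94, 11, "dwarf3", 111, 8, 18, True),
    ("dwarf3", "cell_thickness", "um", "W23xL317", 18.1, 0.9, "dwarf3", 19.5, 0.5, 8, True),
    ("dwarf3", "length_width_ratio", "-", "W23xL317", 14.8, 1.2, "dwarf3", 5.6, 0.3, -62, True),
    ("dwarf3", "length_thickness_ratio", "-", "W23xL317", 4000, 100, "dwarf3", 1300, 100, -68, True),
    ("dwarf3", "width_thickness_ratio", "-", "W23xL317", 250, 30, "dwarf3", 220, 20, -12, True),
    ("ga20ox", "leaf_length", "mm", "B104", 242, 25, "UBI::GA20OX-1", 364, 9, 50, True),
    ("ga20ox", "cell_length", "um", "B104", 134, 3, "UBI::GA20OX-1", 138, 5, 3, True),
    ("ga20ox", "leaf_width", "mm", "B104", 15.7, 0.4, "UBI::GA20OX-1", 13.2, 0.7, -16, True),
    ("ga20ox", "cell_width", "um", "B104", 23.6, 0.9, "UBI::GA20OX-1", 19.7, 0.9, -16, False),
    ("ga20ox", "leaf_thickness", "um", "B104", 113, 8, "UBI::GA20OX-1", 96, 5, -15, True),
    ("ga20ox", "cell_thickness", "um", "B104", 18.5, 0.5, "UBI::GA20OX-1", 17.3, 0.6, -6, True),
    ("ga20ox", "length_width_ratio", "-", "B104", 13.3, 0.6, "UBI::GA20OX-1", 23.4, 0.8, 76, True),
    ("ga20ox", "length_thickness_ratio", "-", "B104", 2200, 200, "UBI::GA20OX-1", 3300, 200, 51, False),
    ("ga20ox", "width_thickness_ratio", "-", "B104", 140, 10, "UBI::GA20OX-1", 140, 10, 0, True),
]

_COLUMNS = [
    "pair", "trait", "unit", "control", "control_mean", "control_se",
    "treatment", "treatment_mean", "treatment_se", "percent_reported",
    "consistent",
]


def leaf_dimensions_reference() -> pd.DataFrame:
    """Leaf/cell dimension means +/- SE for the two gibberellin contrasts."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
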