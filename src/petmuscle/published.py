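"""Reference values from the published clinical cohort this workflow mirrors.

A retrospective whole-body [18F]-FDG PET/CT study of 39 subjects (8 non-RMD
controls, 11 rheumatoid arthritis, 10 osteoarthritis, 10 idiopathic
inflammatory myopathy) reported per-muscle visual pattern counts and a
fixed-vs-hotspot Bland–Altman comparison.  The printed summary numbers are
kept here as machine-readable inputs for consistency checks; they are not
used to calibrate anything.
"""

from __future__ import annotations

import pandas as pd

#: visual pattern counts per muscle x side x group: (homogeneous, heterogeneous).
#: One IIM scan did not include the left arm, hence left triceps/biceps sum to 38.
PATTERN_COUNTS = {
    # (muscle, side): {group: (homogeneous, heterogeneous)}
    ("quadriceps", "R"): {"control": (2, 6), "RA": (0, 11), "OA": (0, 10), "IIM": (0, 10)},
    ("quadriceps", "L"): {"control": (3, 5), "RA": (0, 11), "OA": (0, 10), "IIM": (0, 10)},
    ("hamstrings", "R"): {"control": (1, 7), "RA": (0, 11), "OA": (0, 10), "IIM": (0, 10)},
    ("hamstrings", "L"): {"control": (2, 6), "RA": (0, 11), "OA": (0, 10), "IIM": (3, 7)},
    ("triceps", "R"): {"control": (7, 1), "RA": (6, 5), "OA": (5, 5), "IIM": (4, 6)},
    ("triceps", "L"): {"control": (6, 2), "RA": (9, 2), "OA": (6, 4), "IIM": (2, 7)},
    ("biceps", "R"): {"control": (7, 1), "RA": (3, 8), "OA": (5, 5), "IIM": (4, 6)},
    ("biceps", "L"): {"control": (7, 1), "RA": (5, 6), "OA": (7, 3), "IIM": (1, 8)},
    ("psoas", "R"): {"control": (7, 1), "RA": (2, 9), "OA": (3, 7), "IIM": (4, 6)},
    ("psoas", "L"): {"control": (7, 1), "RA": (4, 7), "OA": (4, 6), "IIM": (5, 5)},
    ("deltoid", "R"): {"control": (7, 1), "RA": (2, 9), "OA": (2, 8), "IIM": (3, 7)},
    ("deltoid", "L"): {"control": (6, 2), "RA": (2, 9), "OA": (3, 7), "IIM": (2, 8)},
}

#: reported fixed-minus-hotspot Bland–Altman summary (SUV units)
BLAND_ALTMAN_BIAS = -0.147
BLAND_ALTMAN_UPPER = 0.117

#: reported hotspot-method fold-increases vs controls in IIM
IIM_FOLD_VS_CONTROL = {"psoas": 2.2, "hamstrings": 1.5, "quadriceps": 2.0}

GROUP_SIZES = {"control": 8, "RA": 11, "OA": 10, "IIM": 10}


def pattern_scores_frame() -> pd.DataFrame:
    """Expand the published counts into one row per scored muscle.

    Returns a DataFrame with columns group/muscle/side/pattern suitable for
    :func:`petmuscle.qualitative.tabulate`.
    """
    rows = []
    for (muscle, side), per_group in PATTERN_COUNTS.items():
        for group, (homo, hetero) in per_group.items():
            rows.extend(
                {"group": group, "muscle": muscle, "side": side, "pattern": "homogeneous"}
                for _ in range(homo)
            )
            rows.extend(
                {"group": group, "muscle": muscle, "side": side, "pattern": "heterogeneous"}
                for _ in range(hetero)
            )
    return pd.DataFrame(rows)
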