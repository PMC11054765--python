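"""Published reference inputs for the two-cohort offloading study.

Small printed tables from the published two-cohort feasibility study of CPTS
in diabetes-related plantar foot ulcers (Australian cohort n=13, Netherlands
cohort n=12), embedded here as analysis inputs:

- baseline-characteristic contingency tables comparing AU participants with
  complete CPTS data (n=5) against those without (n=8);
- the cohort medians/IQRs of the CPTS factors, used as the default parameter
  ranges of the synthetic generator (:mod:`cpts.synth`).

Rows/columns are labelled; counts are participants.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["cpts_availability_tables", "factor_reference_ranges"]


def cpts_availability_tables() -> dict[str, pd.DataFrame]:
    """Contingency tables: CPTS-data-available (n=5) vs not available (n=8).

    Each DataFrame has columns ``available`` / ``not_available`` and one row
    per category.  The ``ulcer_site`` table includes an all-zero midfoot row
    (no midfoot ulcers in this cohort), which Pearson chi-square drops.
    """
    cols = ["available", "not_available"]

    def t(rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    return {
        "sex": t({"female": [2, 2], "male": [3, 6]}),
        "ulcer_history": t({"yes": [4, 8], "no": [1, 0]}),
        "amputation_history": t({"yes": [1, 5], "no": [4, 3]}),
        "peripheral_artery_disease": t({"yes": [1, 0], "no": [4, 8]}),
        "nephropathy": t({"yes": [2, 0], "no": [3, 8]}),
        "retinopathy": t({"yes": [2, 0], "no": [3, 8]}),
        "ischemia": t({"yes": [1, 0], "no": [4, 8]}),
        "offloading_device": t({"knee_high": [1, 1],
                                "ankle_high": [0, 3],
                                "custom_insoles_or_footwear": [4, 4]}),
        "ulcer_site": t({"hallux": [0, 3], "forefoot": [4, 4],
                         "midfoot": [0, 0], "rearfoot": [1, 1]}),
    }


def factor_reference_ranges() -> dict[str, dict]:
    """Cohort medians and [p25; p75] of the CPTS factors, per study style.

    Keys per factor: (median, p25, p75).  Units: PTI kPa.s, PPP kPa, strides
    per day, adherence fraction, TSR dimensionless.
    """
    return {
        "au": {
            "pti_in_device": (66.2, 60.0, 74.7),
            "ppp_in_device": (140.6, 110.9, 302.7),
            "pti_non_device": (72.2, 67.2, 86.3),     # regular footwear
            "ppp_non_device": (178.7, 141.4, 236.4),
            "daily_strides": (7444, 1015, 12456),
            "adherence": (0.509, 0.266, 0.687),
            "tsr_in_device": (0.66, 0.30, 1.07),
            "tsr_non_device": (1.45, -0.15, 2.54),
        },
        "nl": {
            "pti_in_device": (64.7, 48.5, 111.0),
            "ppp_in_device": (119.4, 81.8, 179.8),
            "pti_non_device": (495.2, 235.7, 626.1),  # barefoot platform
            "ppp_non_device": (646.3, 446.0, 923.8),
            "daily_strides": (2146, 1400, 4232),
            "adherence": (0.481, 0.168, 0.855),
            "tsr_in_device": None,                    # thermal not collected
            "tsr_non_device": None,
        },
    }
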