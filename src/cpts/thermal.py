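"""Thermal stress response (TSR): a surrogate for plantar shear stress.

Walking warms the plantar skin; the relative pre-to-post-walk temperature rise
at the ulcer site, normalised by the same rise at the mirrored location on the
contralateral foot, indexes how much frictional/shear work the ulcer site
absorbed relative to a within-subject control:

    TSR = [(post - pre) / pre]_index / [(post - pre) / pre]_contralateral

Temperatures enter in degrees Celsius exactly as measured (no Kelvin
conversion): the ratio-of-relative-changes is defined on the measured unit
and its typical magnitudes (~0.3-1.5) are on the Celsius scale.  The
definition is therefore *not* translation invariant -- adding a constant to
all four temperatures changes the value.  That is a property of the
definition, documented rather than "corrected" here.  Negative values (index
site cooled while the contralateral site warmed, or vice versa) are legal and
propagate into CPTS model 2 with a flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, UndefinedTSRError
from .types import Condition, ThermalReadingPair

__all__ = ["ThermalStressResponse", "thermal_stress_response", "roi_mean_temperature"]


@dataclass
class ThermalStressResponse:
    value: float
    condition: Condition

    @property
    def negative(self) -> bool:
        return self.value < 0


def thermal_stress_response(pair: ThermalReadingPair) -> ThermalStressResponse:
    """Evaluate the TSR ratio for one condition.

    Raises
    ------
    UndefinedTSRError
        If the contralateral temperature did not change (zero denominator).
    InputError
        If a pre-walk temperature is 0 degC (relative change undefined).
    """
    if pair.index_pre == 0 or pair.contra_pre == 0:
        raise InputError("pre-walk temperature of 0 degC: relative change undefined")
    contra_rel = (pair.contra_post - pair.contra_pre) / pair.contra_pre
    if contra_rel == 0:
        raise UndefinedTSRError(
            "contralateral temperature unchanged; TSR undefined"
        )
    index_rel = (pair.index_post - pair.index_pre) / pair.index_pre
    return ThermalStressResponse(value=index_rel / contra_rel, condition=pair.condition)


def roi_mean_temperature(readings, roi=None) -> float:
    """Arithmetic mean temperature over a region of interest.

    ``readings`` is an array of per-pixel/per-spot temperatures; ``roi`` an
    optional index array selecting the region (all readings if omitted).
    """
    arr = np.asarray(readings, dtype=float)
    if roi is not None:
        arr = arr[np.asarray(roi, dtype=int)]
    if arr.size == 0:
        raise InputError("empty ROI")
    return float(arr.mean())
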