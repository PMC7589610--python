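"""Reference cohort statistics for the 20-firefighter fitness study.

The study cohort's per-predictor mean, maximum and minimum (and the derived
range) are the only published summaries of the raw measurements; they anchor
the synthetic-data generator's default predictor ranges and the perturbation
grid used by the sensitivity analysis.

Predictors, in fixed order:

==== ==========================  ===========
X1   body weight                 kg
X2   maximum oxygen uptake       mL/kg/min
X3   body fat percentage         %
X4   upper-body peak power       W
X5   lower-body peak power       W
==== ==========================  ===========

Responses Y1..Y7 are completion times (seconds) of seven simulated
firefighting tasks: rope climb, 200 m loaded round trip, 60 m ladder carry,
loaded stair climb, 400 m evacuation with supplies, 5 km run with air
respirator, 100 m run with water hose.
"""

from __future__ import annotations

import numpy as np

PREDICTOR_NAMES: tuple[str, ...] = ("X1", "X2", "X3", "X4", "X5")
PREDICTOR_LABELS: tuple[str, ...] = (
    "weight",
    "vo2max",
    "body_fat",
    "upper_body_power",
    "lower_body_power",
)
PREDICTOR_UNITS: tuple[str, ...] = ("kg", "mL/kg/min", "%", "W", "W")

RESPONSE_NAMES: tuple[str, ...] = ("Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "Y7")
RESPONSE_LABELS: tuple[str, ...] = (
    "rope_climb",
    "run_200m_load",
    "run_60m_ladder",
    "climb_stairs_load",
    "evacuation_400m",
    "run_5km_respirator",
    "run_100m_hose",
)
RESPONSE_UNITS: tuple[str, ...] = ("s",) * 7

#: Published per-predictor summaries of the study cohort (n = 20).
COHORT_X_AVE = np.array([69.0, 46.85, 14.655, 675.35, 1705.0])
COHORT_X_MAX = np.array([90.0, 62.0, 22.2, 921.0, 2564.0])
COHORT_X_MIN = np.array([56.0, 29.0, 7.7, 483.0, 1408.0])

COHORT_N = 20


def cohort_summary():
    """Predictor summary of the study cohort as a :class:`PredictorSummary`.

    The range row is recomputed as ``x_max - x_min``, never stored.
    """
    from .dataset import PredictorSummary

    return PredictorSummary(
        x_names=PREDICTOR_NAMES,
        x_ave=COHORT_X_AVE.copy(),
        x_max=COHORT_X_MAX.copy(),
        x_min=COHORT_X_MIN.copy(),
    )
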