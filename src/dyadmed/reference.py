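"""Published estimates from the heart-failure dyad study that motivates the
package's worked examples.

A cross-sectional study of 312 Danish heart-failure patient / nearest-relative
dyads fitted this APIMeM (perceived social support -> family health -> family
functioning) and printed the twelve unstandardized path coefficients together
with scale descriptives.  These numbers serve two roles here: as the inputs of
the deterministic effect-decomposition worked example, and as the default
"true" parameter values of the synthetic-data generator, so that simulations
run at a realistic effect-size regime.
"""

from __future__ import annotations

import numpy as np

from .estimate import PathCoefficients

#: dyads analysed / eligible / excluded for incomplete data
N_DYADS = 312
N_ELIGIBLE_DYADS = 320
N_EXCLUDED_DYADS = 8

#: unstandardized path estimates (role subscript = receiver; 1 patient, 2 relative)
STUDY_PATHS = PathCoefficients(
    a_A1=0.107, a_P1=0.038, a_A2=0.180, a_P2=-0.046,
    b_A1=0.556, b_P1=0.236, b_A2=0.752, b_P2=0.099,
    cp_A1=0.105, cp_P1=-0.020, cp_A2=-0.002, cp_P2=-0.003,
)

#: scale mean +/- SD per role: (patient, relative)
STUDY_DESCRIPTIVES = {
    "social_support": {"patient": (83.1, 22.0), "nearest_relative": (78.7, 22.2)},
    "family_health": {"patient": (108.7, 11.4), "nearest_relative": (106.9, 11.9)},
    "family_functioning": {"patient": (90.6, 13.8), "nearest_relative": (89.6, 13.8)},
}

#: empirical distinguishability test as printed
STUDY_DISTINGUISHABILITY = {"chi2": 14.23, "df": 6, "p": 0.027, "rmsea": 0.066}

#: overall equation-level fit
STUDY_R2 = 0.17

#: power-analysis inputs: 12-predictor linear regression at alpha .05
STUDY_POWER_SPEC = {"n": N_DYADS, "predictors": 12, "alpha": 0.05, "f2": 0.09}


def study_exog_moments() -> tuple[np.ndarray, np.ndarray]:
    """Means and SDs of (x1, x2) = patient and relative social support."""
    d = STUDY_DESCRIPTIVES["social_support"]
    means = np.array([d["patient"][0], d["nearest_relative"][0]])
    sds = np.array([d["patient"][1], d["nearest_relative"][1]])
    return means, sds


def study_endogenous_means() -> np.ndarray:
    """Means of (m1, m2, y1, y2)."""
    h = STUDY_DESCRIPTIVES["family_health"]
    f = STUDY_DESCRIPTIVES["family_functioning"]
    return np.array([h["patient"][0], h["nearest_relative"][0],
                     f["patient"][0], f["nearest_relative"][0]])
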