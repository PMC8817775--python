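"""Published quantities of the MDR-TB community-based DOT preference study.

These are the study's printed inputs and results, shipped so the pipeline can
be exercised end-to-end without the (non-deposited) raw choice data: the
respondent covariate marginals, the mixed-logit population parameters used as
the synthetic data-generating process, and the full-precision utility
equation used for care-model ranking.
"""

from __future__ import annotations

import numpy as np

from .postestimation import UtilityEquation
from .simulate import PopulationPreferences

__all__ = [
    "STUDY_MARGINALS",
    "study_population",
    "study_equation",
    "reported_coefficients_2dp",
]

#: Respondent covariate marginals (counts out of 103 interviewed patients).
#: One participant's months-on-treatment value is missing.
STUDY_MARGINALS: dict[str, dict[str, int]] = {
    "gender": {"female": 43, "male": 60},
    "age_group": {"20-34": 42, ">=35": 61},
    "hiv_status": {"negative": 63, "positive": 40},
    "months_group": {"<6": 31, ">=6": 71, None: 1},
}

_LABELS = ("asc", "c_chw", "c_expert", "l_home", "s_phcall", "s_tvouch")


def study_population() -> PopulationPreferences:
    """Mixed-logit population: reported means and heterogeneity SDs.

    Coefficient means (ASC 0.52; CHW 1.13; expert client 0.89; home 1.25;
    phone call 0.70; travel voucher 1.35) and the SDs of the normal random
    coefficients (ASC fixed; 1.85, 1.77, 1.19, 0.19, 0.55).
    """
    return PopulationPreferences(
        mu=np.array([0.52, 1.13, 0.89, 1.25, 0.70, 1.35]),
        sigma=np.array([0.0, 1.85, 1.77, 1.19, 0.19, 0.55]),
        labels=_LABELS,
    )


def study_equation() -> UtilityEquation:
    """Full-precision utility equation used to score and rank care models:

    V = 0.5230616 + 1.132371 c_chw + 0.8881919 c_expert + 1.250887 l_home
        + 0.7014401 s_phcall + 1.346391 s_tvouch
    """
    return UtilityEquation(
        constant=0.5230616,
        coefficients={
            "c_chw": 1.132371,
            "c_expert": 0.8881919,
            "l_home": 1.250887,
            "s_phcall": 0.7014401,
            "s_tvouch": 1.346391,
        },
    )


def reported_coefficients_2dp() -> UtilityEquation:
    """The same equation at the two-decimal precision of the results table.

    These are the coefficients the published relative-importance figures
    (36.2 / 33.5 / 30.3 percent) derive from.
    """
    return UtilityEquation(
        constant=0.52,
        coefficients={
            "c_chw": 1.13,
            "c_expert": 0.89,
            "l_home": 1.25,
            "s_phcall": 0.70,
            "s_tvouch": 1.35,
        },
    )
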