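"""Default study conditions for the simulated twin intervention cohort.

These constants describe a 10-week online positive-activity intervention in
a cohort of adolescent same-sex twin pairs, with outcomes assessed at four
occasions (weeks 1, 4, 7 and 10: baseline, end of control phase, end of
intervention phase, follow-up).  They are the generator defaults used by the
analysis scripts and the acceptance checks.

``WELLBEING_COMPONENTS`` and ``MENTALHEALTH_COMPONENTS`` are standardized
variance-component structures (proportions of phenotypic variance
contributed by each triangular A/C/E factor at each stage) typical of
adolescent subjective well-being and internalizing mental health: moderate,
stable heritability transmitted almost entirely from baseline, a small
shared-environment contribution, and non-shared environmental influence
with fresh innovations at every stage — notably a large intervention-stage
E innovation.
"""

from __future__ import annotations

import numpy as np

from .params import CholeskyACEParams, MeanTrajectory, proportions_to_loadings

__all__ = [
    "N_MZ_PAIRS",
    "N_DZ_PAIRS",
    "AGE_MEAN",
    "AGE_SD",
    "FEMALE_FRACTION",
    "STAGE_WEEKS",
    "STAGE_NAMES",
    "WELLBEING_COMPONENTS",
    "MENTALHEALTH_COMPONENTS",
    "default_params",
    "default_trajectory",
]

N_MZ_PAIRS = 167
N_DZ_PAIRS = 208
AGE_MEAN = 16.55
AGE_SD = 0.51
#: Pooled across the MZ (59.8% female) and DZ (56.5% female) groups.
FEMALE_FRACTION = 0.58
STAGE_WEEKS = (1.0, 4.0, 7.0, 10.0)
STAGE_NAMES = ("baseline", "control", "intervention", "followup")

#: Per-stage observation probabilities matching typical attrition
#: (complete-pair counts of roughly 165/160/155/164 out of 167 MZ pairs).
STAGE_RETENTION = (0.995, 0.985, 0.97, 0.99)

# Standardized contributions: rows = stages, columns = factors (triangular).
WELLBEING_COMPONENTS = {
    "a": np.array(
        [
            [0.48, 0.00, 0.00, 0.00],
            [0.48, 0.02, 0.00, 0.00],
            [0.41, 0.03, 0.01, 0.00],
            [0.44, 0.03, 0.01, 0.00],
        ]
    ),
    "c": np.array(
        [
            [0.07, 0.00, 0.00, 0.00],
            [0.05, 0.00, 0.00, 0.00],
            [0.06, 0.00, 0.00, 0.00],
            [0.03, 0.00, 0.00, 0.00],
        ]
    ),
    "e": np.array(
        [
            [0.44, 0.00, 0.00, 0.00],
            [0.23, 0.22, 0.00, 0.00],
            [0.22, 0.06, 0.20, 0.00],
            [0.21, 0.07, 0.04, 0.18],
        ]
    ),
}

MENTALHEALTH_COMPONENTS = {
    "a": np.array(
        [
            [0.24, 0.00, 0.00, 0.00],
            [0.26, 0.09, 0.00, 0.00],
            [0.34, 0.01, 0.01, 0.00],
            [0.27, 0.01, 0.00, 0.00],
        ]
    ),
    "c": np.array(
        [
            [0.13, 0.00, 0.00, 0.00],
            [0.05, 0.00, 0.00, 0.00],
            [0.01, 0.00, 0.00, 0.00],
            [0.01, 0.03, 0.02, 0.00],
        ]
    ),
    "e": np.array(
        [
            [0.63, 0.00, 0.00, 0.00],
            [0.20, 0.41, 0.00, 0.00],
            [0.16, 0.09, 0.38, 0.00],
            [0.17, 0.08, 0.04, 0.38],
        ]
    ),
}


def default_params(outcome: str = "wellbeing") -> CholeskyACEParams:
    """Generating Cholesky ACE loadings for a named outcome composite."""
    tables = {"wellbeing": WELLBEING_COMPONENTS, "mentalhealth": MENTALHEALTH_COMPONENTS}
    try:
        t = tables[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {sorted(tables)}") from None
    return proportions_to_loadings(t["a"], t["c"], t["e"])


def default_trajectory() -> MeanTrajectory:
    """Flat control phase, then +0.07 SD per occasion from the intervention on."""
    return MeanTrajectory(
        baseline_mean=0.0,
        control_increment=0.0,
        intervention_increment=0.07,
        age_effect=0.0,
        sex_effect=0.0,
        stage_times=STAGE_WEEKS,
    )
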