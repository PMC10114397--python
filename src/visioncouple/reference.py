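"""Reference statistics of the clinical cohort the package defaults emulate.

These constants summarise the training cohort behind the method's published
evaluation: 46 children (ages 4-12) with unilateral anisometropic amblyopia
who completed dichoptic push-pull perceptual training for 6-12 months, with
the four-test battery taken before and after. They are the default targets
of the synthetic-cohort generator and the inputs to summary-level
reconstructions (variation coefficients, t statistics).

``REFERENCE_WEIGHTS`` and ``REFERENCE_WEIGHTS_WITH_VALIDATION`` are the
composite-index weights reported for that cohort. They are retained for
comparison only: the published summary statistics do not determine them
(an unstated normalisation of the raw per-subject data was evidently
involved), so nothing in this package computes with them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "INDICATORS",
    "REFERENCE_N",
    "REFERENCE_MEANS",
    "REFERENCE_SDS",
    "REFERENCE_CORRELATION",
    "REFERENCE_VARIATION_COEFFICIENTS",
    "REFERENCE_T_MAGNITUDES",
    "REFERENCE_VERTICAL_PEP_T",
    "REFERENCE_WEIGHTS",
    "REFERENCE_WEIGHTS_WITH_VALIDATION",
    "VALIDATION_REFERENCE_CI",
]

#: Canonical indicator order used throughout the package.
INDICATORS = ("visual_acuity", "brbp", "horizontal_pep", "stereoacuity")

#: Training-cohort size.
REFERENCE_N = 46

#: Mean post-minus-pre difference per indicator (logMAR, levels, deg, levels).
REFERENCE_MEANS = (-0.38, -1.48, -0.60, 0.85)

#: Sample SD of the difference per indicator.
REFERENCE_SDS = (0.26, 2.02, 1.31, 1.26)

#: Pearson correlation between the four difference scores.
REFERENCE_CORRELATION = np.array(
    [
        [1.0000, 0.1004, -0.1891, -0.1906],
        [0.1004, 1.0000, 0.0722, -0.1537],
        [-0.1891, 0.0722, 1.0000, 0.0408],
        [-0.1906, -0.1537, 0.0408, 1.0000],
    ]
)

#: Variation coefficients as tabulated for the cohort (mean/SD convention).
REFERENCE_VARIATION_COEFFICIENTS = (-1.46, -0.73, -0.46, 0.67)

#: |t| of the paired pre/post test per indicator (df = 45).
REFERENCE_T_MAGNITUDES = {
    "visual_acuity": 9.766,
    "brbp": 4.965,
    "horizontal_pep": 3.094,
    "stereoacuity": 4.548,
}

#: Vertical PEP paired test: not significant, hence excluded from coupling.
REFERENCE_VERTICAL_PEP_T = {"t": 1.520, "p": 0.136}

#: Reported composite-index weights (training cohort). Reference only.
REFERENCE_WEIGHTS = (0.2154, 0.2575, 0.1724, 0.3547)

#: Reported weights after adding the 8 validation subjects. Reference only.
REFERENCE_WEIGHTS_WITH_VALIDATION = (0.2221, 0.2643, 0.1633, 0.3504)

#: Reported coupling indices of the 8-subject validation cohort. The scoring
#: formula behind them was not disclosed; this package checks the narrated
#: ordering relations (S1 maximal, S5 below S4), never these values.
VALIDATION_REFERENCE_CI = {
    "S1": 0.5210,
    "S2": 0.3502,
    "S3": 0.3002,
    "S4": 0.3468,
    "S5": 0.1897,
    "S6": 0.1784,
    "S7": 0.1389,
    "S8": 0.2066,
}
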