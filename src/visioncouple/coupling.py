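"""Per-subject coupling index: a weighted composite of oriented difference scores.

A subject's four difference scores do not share an "up is better"
direction: treatment benefit is a *decrease* in logMAR acuity, interocular
BRBP gap and horizontal PEP (cost-type indicators) but an *increase* in
stereo level (benefit-type). Scores are first oriented so larger is always
better, then normalised cohort-relative — min-max to [0, 1] per column by
default (the normalisation native to the CRITIC literature), or Z-score —
and combined as ci_i = sum_j w_j * u_ij with CRITIC weights.

Under min-max the index lands in [0, 1]: a subject best-in-cohort on every
indicator scores 1, worst-in-cohort on every indicator scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateNormalizationError, IncompleteRecordError
from .vision_metrics import DifferenceVector

__all__ = [
    "DEFAULT_ORIENTATION",
    "CouplingScore",
    "orient_differences",
    "orient_matrix",
    "coupling_index",
    "rank_subjects",
]

#: Benefit/cost direction of each coupled indicator: cost means a decrease
#: is an improvement (negated on orientation), benefit means an increase is.
DEFAULT_ORIENTATION: Mapping[str, str] = {
    "visual_acuity": "cost",
    "brbp": "cost",
    "horizontal_pep": "cost",
    "stereoacuity": "benefit",
}

NORMALIZATIONS = ("minmax", "zscore")


@dataclass(frozen=True)
class CouplingScore:
    """One subject's composite efficacy score and its per-indicator parts."""

    subject_id: str
    ci: float
    normalization: str
    components: tuple[float, ...]  # w_j * u_ij, summing to ci

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(float(c) for c in self.components))


def _check_orientation(spec: Mapping[str, str], labels: Sequence[str]) -> np.ndarray:
    signs = np.empty(len(labels))
    for j, label in enumerate(labels):
        if label not in spec:
            raise IncompleteRecordError(f"orientation missing for indicator {label!r}")
        direction = spec[label]
        if direction not in ("benefit", "cost"):
            raise ValueError(f"direction must be 'benefit' or 'cost', got {direction!r}")
        signs[j] = 1.0 if direction == "benefit" else -1.0
    return signs


def orient_differences(
    d: DifferenceVector, spec: Mapping[str, str] = DEFAULT_ORIENTATION
) -> np.ndarray:
    """Orient one subject's difference vector so larger is always better."""
    raw = np.asarray(d.as_tuple(), dtype=float)
    signs = _check_orientation(spec, list(DEFAULT_ORIENTATION))
    return signs * raw


def orient_matrix(
    X: np.ndarray,
    labels: Sequence[str],
    spec: Mapping[str, str] = DEFAULT_ORIENTATION,
) -> np.ndarray:
    """Column-wise orientation of a cohort difference matrix."""
    X = np.asarray(X, dtype=float)
    return _check_orientation(spec, labels) * X


def coupling_index(
    oriented: np.ndarray,
    weights: Sequence[float] | np.ndarray,
    subject_ids: Sequence[str],
    normalization: str = "minmax",
) -> list[CouplingScore]:
    """Composite index per subject from cohort-oriented scores.

    ``oriented`` is the m x n matrix of benefit-oriented difference scores;
    normalisation is cohort-relative per column. Weights must sum to 1 and
    the cohort must have at least 2 subjects (cohort-relative normalisation
    is meaningless otherwise). Min-max requires non-constant columns.
    """
    oriented = np.asarray(oriented, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if oriented.ndim != 2:
        raise ValueError("oriented scores must be a 2-D matrix")
    m, n = oriented.shape
    if m < 2:
        raise ValueError(f"cohort-relative normalization needs m >= 2 subjects, got {m}")
    if weights.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {weights.shape}")
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")
    if len(subject_ids) != m:
        raise ValueError("subject_ids must match the number of rows")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}")

    if normalization == "minmax":
        lo = oriented.min(axis=0)
        hi = oriented.max(axis=0)
        span = hi - lo
        for j in range(n):
            if span[j] == 0.0:
                raise DegenerateNormalizationError(
                    f"column {j} is constant across the cohort; min-max normalization undefined"
                )
        U = (oriented - lo) / span
    else:
        sds = oriented.std(axis=0, ddof=1)
        for j in range(n):
            if sds[j] == 0.0:
                raise DegenerateNormalizationError(
                    f"column {j} is constant across the cohort; Z-score normalization undefined"
                )
        U = (oriented - oriented.mean(axis=0)) / sds

    contributions = U * weights
    scores = [
        CouplingScore(
            subject_id=str(sid),
            ci=float(contributions[i].sum()),
            normalization=normalization,
            components=tuple(contributions[i]),
        )
        for i, sid in enumerate(subject_ids)
    ]
    return scores


def rank_subjects(scores: Sequence[CouplingScore]) -> list[CouplingScore]:
    """Scores in descending index order; ties break by subject id."""
    if not scores:
        raise ValueError("cannot rank an empty score list")
    return sorted(scores, key=lambda s: (-s.ci, s.subject_id))
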