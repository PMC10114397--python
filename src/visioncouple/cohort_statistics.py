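"""Paired pre/post screening statistics and Pearson correlation machinery.

Each indicator's difference scores are screened with a paired t test
(equivalently, a one-sample t test of the post-minus-pre differences
against zero): t = d_bar / (s_d / sqrt(n)) with the sample (n-1) standard
deviation and a two-sided p from Student's t on n-1 degrees of freedom.
Only indicators whose change is significant enter the composite index;
in the reference cohort that screens out vertical PEP.

The correlation matrix of the difference scores is the same object the
CRITIC weighting consumes; Pearson correlation is invariant under the
Z-score standardization CRITIC applies, so it may be computed on raw or
standardized columns interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "PairedTestResult",
    "CorrelationMatrix",
    "paired_t",
    "t_from_summary",
    "pearson_correlation_matrix",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Summary of a paired (pre/post) t test on one indicator."""

    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    sd_diff: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labelled Pearson correlation matrix (symmetric, unit diagonal)."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {values.shape}")
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count must match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def paired_t(differences: Sequence[float] | np.ndarray) -> PairedTestResult:
    """Paired t test of pre/post differences against zero.

    Requires n >= 2 and non-constant differences; a constant sample leaves
    t undefined and raises :class:`DegenerateDataError` (distinct from the
    ``ValueError`` raised for n < 2).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    n = d.size
    if n < 2:
        raise ValueError(f"paired t test needs n >= 2, got n={n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError(
            "all differences identical: paired t statistic undefined (zero SD)"
        )
    t = mean * math.sqrt(n) / sd
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTestResult(t_stat=t, df=df, p_value=p, mean_diff=mean, sd_diff=sd, n=n)


def t_from_summary(mean_diff: float, sd_diff: float, n: int) -> float:
    """Paired t statistic from summary statistics: mean * sqrt(n) / SD.

    Agrees exactly with :func:`paired_t` on any dataset having these
    summaries; used to reconstruct published t values from tabulated
    means and SDs.
    """
    if n < 2:
        raise ValueError(f"paired t test needs n >= 2, got n={n}")
    if not sd_diff > 0:
        raise DegenerateDataError(f"sd_diff must be > 0, got {sd_diff}")
    return mean_diff * math.sqrt(n) / sd_diff


def pearson_correlation_matrix(
    X: np.ndarray, labels: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix of the columns of an m x n data matrix.

    Requires m >= 3 rows and nonzero variance in every column; a constant
    column is reported by name. The result is invariant under per-column
    positive affine transforms (so raw and Z-scored data give the same R).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("data matrix must be two-dimensional")
    m, n = X.shape
    if m < 3:
        raise ValueError(f"correlation needs at least 3 rows, got m={m}")
    if labels is None:
        labels = tuple(f"col{j}" for j in range(n))
    labels = tuple(labels)
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0.0:
            raise DegenerateDataError(
                f"column {labels[j]!r} has zero variance; correlation undefined"
            )
    R = np.corrcoef(X, rowvar=False)
    # guard tiny numerical excursions outside [-1, 1]
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(values=R, labels=labels)
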