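"""CRITIC objective weighting (Criteria Importance Through Inter-criteria Correlation).

CRITIC derives indicator weights from the data alone, combining two signals:

* **contrast intensity** — how much an indicator varies across subjects,
  captured by its variation coefficient v_j;
* **conflict** — how independent an indicator is from the others, captured
  by the independence coefficient eta_j = sum_k (1 - |r_kj|) over the
  correlation matrix R (the self term contributes 0, so eta_j lies in
  [0, n-1]).

The information volume D_j = f(v_j) * eta_j multiplies the two, and weights
are the normalised volumes w_j = D_j / sum(D).

Two documented ambiguities in the source tabulation are exposed as options
rather than resolved silently:

* ``convention`` — the variation coefficient is *defined* as SD/mean
  (``"definitional"``), but the tabulated reference column is mean/SD (its every
  entry equals mean/SD to the printed precision). ``"table"`` reproduces
  the tabulation and is the default.
* ``magnitude_policy`` — with post-minus-pre differences, three of the four
  reference v values are negative; taking D_j = v_j * eta_j literally would
  produce negative weights. ``"abs"`` (default) uses |v_j| so weights are
  non-negative; ``"signed"`` keeps the literal product for fidelity
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_statistics import CorrelationMatrix, pearson_correlation_matrix
from .errors import DegenerateDataError

__all__ = [
    "DataMatrix",
    "ColumnSummary",
    "CriticResult",
    "standardize",
    "column_summaries",
    "variation_coefficients",
    "independence_coefficients",
    "information_volume",
    "critic_weights",
    "run_critic",
]

V_CONVENTIONS = ("definitional", "table")
MAGNITUDE_POLICIES = ("abs", "signed")


@dataclass(frozen=True)
class DataMatrix:
    """An m x n matrix of subjects (rows) by indicators (columns)."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = values.shape
        if m < 3 or n < 2:
            raise ValueError(f"need at least 3 subjects and 2 indicators, got {m}x{n}")
        if len(self.row_ids) != m or len(self.col_labels) != n:
            raise ValueError("row_ids/col_labels must match matrix shape")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix must not contain missing/non-finite entries")

    @classmethod
    def from_array(cls, values: np.ndarray, col_labels: Sequence[str] | None = None) -> "DataMatrix":
        values = np.asarray(values, dtype=float)
        m, n = values.shape
        if col_labels is None:
            col_labels = [f"col{j}" for j in range(n)]
        return cls(values, tuple(f"r{i}" for i in range(m)), tuple(col_labels))


@dataclass(frozen=True)
class ColumnSummary:
    """Per-indicator mean, sample SD, and both variation-coefficient forms."""

    label: str
    mean: float
    sd: float

    @property
    def v_definitional(self) -> float:
        """Variation coefficient as defined: SD / mean."""
        return self.sd / self.mean

    @property
    def v_table(self) -> float:
        """Variation coefficient as tabulated: mean / SD (reciprocal form)."""
        return self.mean / self.sd


@dataclass(frozen=True)
class CriticResult:
    """All intermediates of a CRITIC run, for reporting and audit."""

    data: DataMatrix
    standardized: np.ndarray
    summaries: tuple[ColumnSummary, ...]
    correlation: CorrelationMatrix
    variation: np.ndarray
    independence: np.ndarray
    information: np.ndarray
    weights: np.ndarray
    convention: str
    magnitude_policy: str

    def weights_by_label(self) -> dict[str, float]:
        return dict(zip(self.data.col_labels, map(float, self.weights)))


def standardize(X: np.ndarray) -> np.ndarray:
    """Z-score each column: (x - column mean) / column sample SD.

    Output columns have mean 0 and sample SD 1. A zero-variance column is
    a :class:`DegenerateDataError` naming the column index.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0.0:
            raise DegenerateDataError(f"column {j} has zero variance; cannot standardize")
    return (X - means) / sds


def column_summaries(X: np.ndarray, labels: Sequence[str] | None = None) -> tuple[ColumnSummary, ...]:
    """Mean and sample SD of each column."""
    X = np.asarray(X, dtype=float)
    if labels is None:
        labels = [f"col{j}" for j in range(X.shape[1])]
    return tuple(
        ColumnSummary(label=str(lab), mean=float(col.mean()), sd=float(col.std(ddof=1)))
        for lab, col in zip(labels, X.T)
    )


def variation_coefficients(
    summaries: Sequence[ColumnSummary], convention: str = "table"
) -> np.ndarray:
    """Variation coefficient of each indicator under the chosen convention.

    ``"definitional"`` returns SD/mean (the definitional form); ``"table"`` returns
    mean/SD (the form the reference tabulation actually printed). A zero
    denominator is degenerate either way.
    """
    if convention not in V_CONVENTIONS:
        raise ValueError(f"convention must be one of {V_CONVENTIONS}, got {convention!r}")
    out = np.empty(len(summaries))
    for j, s in enumerate(summaries):
        denom = s.mean if convention == "definitional" else s.sd
        if denom == 0.0:
            raise DegenerateDataError(
                f"column {s.label!r}: zero {'mean' if convention == 'definitional' else 'SD'} "
                f"under convention {convention!r}"
            )
        out[j] = s.v_definitional if convention == "definitional" else s.v_table
    return out


def independence_coefficients(R: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Independence (conflict) coefficient eta_j = sum_k (1 - |r_kj|).

    The sum runs over all k including k = j, whose term is zero, so each
    eta_j lies in [0, n-1]; larger means less redundant with the rest.
    """
    values = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    return (1.0 - np.abs(values)).sum(axis=0)


def information_volume(
    v: np.ndarray, eta: np.ndarray, magnitude_policy: str = "abs"
) -> np.ndarray:
    """Information volume D_j = f(v_j) * eta_j.

    ``"abs"`` takes f = |.| so that indicators with negative mean change
    still carry positive information; ``"signed"`` keeps f = identity.
    """
    if magnitude_policy not in MAGNITUDE_POLICIES:
        raise ValueError(
            f"magnitude_policy must be one of {MAGNITUDE_POLICIES}, got {magnitude_policy!r}"
        )
    v = np.asarray(v, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if v.shape != eta.shape:
        raise ValueError(f"shape mismatch: v {v.shape} vs eta {eta.shape}")
    return (np.abs(v) if magnitude_policy == "abs" else v) * eta


def critic_weights(D: np.ndarray) -> np.ndarray:
    """Normalise information volumes to weights w_j = D_j / sum(D)."""
    D = np.asarray(D, dtype=float)
    total = D.sum()
    if total == 0.0:
        raise DegenerateDataError("all information volumes are zero: no discriminating information")
    return D / total


def run_critic(
    X: DataMatrix | np.ndarray,
    col_labels: Sequence[str] | None = None,
    *,
    convention: str = "table",
    magnitude_policy: str = "abs",
) -> CriticResult:
    """Full CRITIC chain: standardize, summarise, correlate, weight.

    Every intermediate (standardized matrix, per-column summaries, R, eta,
    D, w) is recorded on the returned :class:`CriticResult`.
    """
    data = X if isinstance(X, DataMatrix) else DataMatrix.from_array(X, col_labels)
    values = data.values
    standardized = standardize(values)
    summaries = column_summaries(values, data.col_labels)
    # Pearson correlation is affine-invariant, so computing it on the
    # standardized matrix equals computing it on the raw columns.
    correlation = pearson_correlation_matrix(standardized, data.col_labels)
    v = variation_coefficients(summaries, convention)
    eta = independence_coefficients(correlation)
    D = information_volume(v, eta, magnitude_policy)
    w = critic_weights(D)
    return CriticResult(
        data=data,
        standardized=standardized,
        summaries=summaries,
        correlation=correlation,
        variation=v,
        independence=eta,
        information=D,
        weights=w,
        convention=convention,
        magnitude_policy=magnitude_policy,
    )
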