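"""Seedable synthetic cohorts matching the reference difference-score structure.

No raw per-subject data accompany the reference cohort — only first and
second moments and the 4x4 correlation of its difference scores. The
minimal-assumption generator consistent with that information is a
Gaussian model: draw correlated standard normals through a Cholesky factor
of the target correlation, rescale to the target SDs and shift to the
target means. Two modes:

* ``continuous`` — the raw Gaussian draws; used for moment/correlation
  recovery checks.
* ``discretized`` — draws snapped to each scale's legal grid (0.1-logMAR
  steps for VA, integers for BRBP gap and stereo level, with the scale
  bounds enforced). Discreteness is imposed post hoc rather than through
  ordinal latent thresholds; the induced bias is small and bounded by
  tests.

``generate_cohort`` additionally realises each difference as an actual
pre/post examination pair on clinically legal grids, so the whole pipeline
(records in, composite index out) can run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import reference
from .critic import DataMatrix
from .errors import SpecError
from .vision_metrics import CHART_LOGMAR_MAX, ExamRecord

__all__ = ["CohortSpec", "generate_differences", "generate_cohort"]

_MAX_RETRIES = 100

# Clinically legal pre-treatment ranges used when realising records:
# amblyopic-eye VA logMAR 0.1..1.0 (0.1 grid), BRBP levels 1..8,
# stereo levels 0..4, PEP 0..3 degrees.
_PRE_VA_MIN, _PRE_VA_MAX = 0.1, 1.0
_PEP_MAX = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Defaults reproduce the reference cohort's tabulated moments and
    correlations. ``seed`` is mandatory: there is no hidden global
    randomness.
    """

    n_subjects: int
    seed: int
    target_means: tuple[float, ...] = reference.REFERENCE_MEANS
    target_sds: tuple[float, ...] = reference.REFERENCE_SDS
    target_correlation: np.ndarray = field(
        default_factory=lambda: reference.REFERENCE_CORRELATION.copy()
    )
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise SpecError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.mode not in ("continuous", "discretized"):
            raise SpecError(f"mode must be 'continuous' or 'discretized', got {self.mode!r}")
        means = np.asarray(self.target_means, dtype=float)
        sds = np.asarray(self.target_sds, dtype=float)
        corr = np.asarray(self.target_correlation, dtype=float)
        object.__setattr__(self, "target_means", tuple(means))
        object.__setattr__(self, "target_sds", tuple(sds))
        object.__setattr__(self, "target_correlation", corr)
        if means.shape != (4,) or sds.shape != (4,):
            raise SpecError("target_means and target_sds must have length 4")
        if np.any(sds <= 0):
            raise SpecError(f"target_sds must be strictly positive, got {tuple(sds)}")
        if corr.shape != (4, 4):
            raise SpecError("target_correlation must be 4x4")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise SpecError("target_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise SpecError("target_correlation must have a unit diagonal")

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.target_correlation)
        except np.linalg.LinAlgError as exc:
            raise SpecError(
                "target_correlation is not positive definite; project it to the "
                "nearest positive-definite correlation matrix before generating"
            ) from exc


def _subject_ids(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"SYN{i + 1:0{width}d}" for i in range(n))


def generate_differences(spec: CohortSpec) -> DataMatrix:
    """Draw an n x 4 difference-score matrix with the spec's target structure.

    Deterministic given the seed. In ``discretized`` mode VA differences
    snap to the 0.1-logMAR grid, BRBP and stereo differences to integers,
    with stereo clipped to [-4, 4] and BRBP to [-7, 7].
    """
    L = spec.cholesky()
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n_subjects, 4))
    X = Z @ L.T
    X = X * np.asarray(spec.target_sds) + np.asarray(spec.target_means)
    if spec.mode == "discretized":
        X[:, 0] = np.round(X[:, 0] / 0.1) * 0.1
        X[:, 1] = np.clip(np.round(X[:, 1]), -7, 7)
        X[:, 3] = np.clip(np.round(X[:, 3]), -4, 4)
    return DataMatrix(
        values=X,
        row_ids=_subject_ids(spec.n_subjects),
        col_labels=reference.INDICATORS,
    )


def _feasible_uniform(rng: np.random.Generator, lo: float, hi: float, what: str) -> float:
    if lo > hi + 1e-9:
        raise SpecError(f"no feasible {what} range [{lo}, {hi}] after clipping")
    return float(rng.uniform(lo, min(hi, max(lo, hi))))


def _realize_subject(
    rng: np.random.Generator, sid: str, d: np.ndarray
) -> tuple[ExamRecord, ExamRecord, np.ndarray]:
    """Build a legal pre/post record pair realising (a clipped version of) d."""
    d_va, d_brbp, d_hpep, d_sa = d

    # VA: post must stay on the chart, pre in the amblyopic range.
    d_va = float(np.clip(d_va, -(_PRE_VA_MAX - (-0.3)), CHART_LOGMAR_MAX - _PRE_VA_MIN))
    d_va = round(round(d_va / 0.1) * 0.1, 10)
    lo = max(_PRE_VA_MIN, -0.3 - d_va)
    hi = min(_PRE_VA_MAX, CHART_LOGMAR_MAX - d_va)
    grid = np.round(np.arange(round(lo * 10), round(hi * 10) + 1) * 0.1, 10)
    pre_va = float(rng.choice(grid))
    post_va = round(pre_va + d_va, 10)

    # BRBP: realise interocular gaps g_pre, g_post = g_pre + d, both in 0..7,
    # then place eye levels; the fellow eye keeps its level across phases and
    # the amblyopic (randomly left or right) eye sits deeper by the gap.
    d_brbp = int(np.clip(round(d_brbp), -7, 7))
    g_lo, g_hi = max(0, -d_brbp), min(7, 7 - d_brbp)
    g_pre = int(rng.integers(g_lo, g_hi + 1))
    g_post = g_pre + d_brbp
    fellow = int(rng.integers(1, 8 + 1 - max(g_pre, g_post)))
    amblyopic_is_right = bool(rng.integers(0, 2))
    pre_eyes = (fellow + g_pre, fellow) if amblyopic_is_right else (fellow, fellow + g_pre)
    post_eyes = (fellow + g_post, fellow) if amblyopic_is_right else (fellow, fellow + g_post)

    # Horizontal PEP: both phases within 0..3 degrees.
    d_hpep = float(np.clip(d_hpep, -_PEP_MAX, _PEP_MAX))
    pre_h = _feasible_uniform(rng, max(0.0, -d_hpep), min(_PEP_MAX, _PEP_MAX - d_hpep), "H-PEP")
    post_h = pre_h + d_hpep
    # Vertical PEP: carried but not part of the difference matrix. The drift
    # emulates the reference cohort's slight, non-significant decrease
    # (paired |t| around 1.5 at n = 46).
    pre_v = float(rng.uniform(0.0, 1.5))
    post_v = float(np.clip(pre_v + rng.normal(-0.07, 0.31), 0.0, _PEP_MAX))

    # Stereo: integer levels, both phases in 0..4.
    d_sa = int(np.clip(round(d_sa), -4, 4))
    pre_sa = int(rng.integers(max(0, -d_sa), min(4, 4 - d_sa) + 1))
    post_sa = pre_sa + d_sa

    pre = ExamRecord.from_raw(
        sid, "pre",
        va_logmar=pre_va, brbp_right=pre_eyes[0], brbp_left=pre_eyes[1],
        pep_h=pre_h, pep_v=pre_v, stereo_level=pre_sa,
    )
    post = ExamRecord.from_raw(
        sid, "post",
        va_logmar=post_va, brbp_right=post_eyes[0], brbp_left=post_eyes[1],
        pep_h=post_h, pep_v=post_v, stereo_level=post_sa,
    )
    return pre, post, np.array([d_va, d_brbp, d_hpep, d_sa])


def generate_cohort(spec: CohortSpec) -> tuple[list[ExamRecord], DataMatrix]:
    """Realise a discretized cohort as paired examination records.

    Returns the records (pre and post per subject) together with the
    realised difference matrix; ``compute_difference_vector`` on each pair
    recovers that matrix exactly, by construction. Requires ``discretized``
    mode. Subjects whose difference cannot be placed on the legal grids are
    re-drawn up to a retry cap.
    """
    if spec.mode != "discretized":
        raise SpecError("generate_cohort requires a discretized-mode spec")
    diffs = generate_differences(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    records: list[ExamRecord] = []
    realized_rows: list[np.ndarray] = []
    for sid, row in zip(diffs.row_ids, diffs.values):
        last_err: Exception | None = None
        for _ in range(_MAX_RETRIES):
            try:
                pre, post, realized = _realize_subject(rng, sid, row)
                break
            except SpecError as exc:  # infeasible placement: re-draw positions
                last_err = exc
        else:
            raise SpecError(f"subject {sid}: no feasible records after {_MAX_RETRIES} tries") from last_err
        records.extend([pre, post])
        realized_rows.append(realized)
    realized_matrix = DataMatrix(
        values=np.vstack(realized_rows),
        row_ids=diffs.row_ids,
        col_labels=diffs.col_labels,
    )
    return records, realized_matrix


def iter_pairs(records: list[ExamRecord]) -> Iterator[tuple[ExamRecord, ExamRecord]]:
    """Yield (pre, post) pairs from a flat record list, in subject order."""
    by_subject: dict[str, dict[str, ExamRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, {})[rec.phase] = rec
    for sid, phases in by_subject.items():
        if "pre" in phases and "post" in phases:
            yield phases["pre"], phases["post"]
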