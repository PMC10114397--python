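"""End-to-end analysis: records -> screening t tests -> CRITIC -> coupling index.

``run_full_report`` reproduces the evaluation sequence on a paired cohort:

1. per-subject difference vectors (post minus pre);
2. paired t tests on the four coupled indicators (plus vertical PEP when
   carried — reported, never coupled);
3. pairwise Pearson correlations of the acuity improvement against the
   other difference scores (reported as a table of r values: the scores
   do not track each other, which is the motivation for coupling them);
4. CRITIC weights on the 4-column difference matrix;
5. per-subject coupling indices under the configured normalisation.

Everything is deterministic given the input and configuration; the report
serialises to JSON losslessly (full-precision floats) with provenance
(configuration, input hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _version
from .cohort_statistics import PairedTestResult, paired_t, pearson_correlation_matrix
from .coupling import DEFAULT_ORIENTATION, CouplingScore, coupling_index, orient_matrix, rank_subjects
from .critic import CriticResult, DataMatrix, run_critic
from .io import cohort_differences
from .reference import INDICATORS
from .vision_metrics import DifferenceVector, ExamRecord

__all__ = ["PipelineConfig", "AnalysisReport", "difference_matrix", "run_full_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults follow the reference analysis: tabulated variation-coefficient
    convention, absolute-magnitude information volumes, cohort min-max
    normalisation, cost orientation for all indicators except stereoacuity,
    and a 0.05 significance screen."""

    v_convention: str = "table"
    magnitude_policy: str = "abs"
    ci_normalization: str = "minmax"
    orientation: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    alpha: float = 0.05
    seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orientation"] = dict(self.orientation)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**d)


def difference_matrix(diffs: Sequence[DifferenceVector]) -> DataMatrix:
    """Stack difference vectors into the m x 4 coupled-indicator matrix."""
    values = np.array([d.as_tuple() for d in diffs], dtype=float)
    return DataMatrix(
        values=values,
        row_ids=tuple(d.subject_id for d in diffs),
        col_labels=INDICATORS,
    )


@dataclass(frozen=True)
class AnalysisReport:
    """Full analysis output; serialises to/from JSON losslessly."""

    config: PipelineConfig
    n_subjects: int
    paired_tests: dict[str, PairedTestResult]
    va_improvement_correlations: dict[str, float]
    critic: CriticResult
    scores: tuple[CouplingScore, ...]
    input_hash: str
    version: str = _version

    def ranking(self) -> list[CouplingScore]:
        return rank_subjects(self.scores)

    def to_dict(self) -> dict:
        crit = self.critic
        return {
            "version": self.version,
            "input_hash": self.input_hash,
            "config": self.config.to_dict(),
            "n_subjects": self.n_subjects,
            "paired_tests": {
                name: dataclasses.asdict(res) for name, res in self.paired_tests.items()
            },
            "va_improvement_correlations": dict(self.va_improvement_correlations),
            "critic": {
                "col_labels": list(crit.data.col_labels),
                "row_ids": list(crit.data.row_ids),
                "values": crit.data.values.tolist(),
                "standardized": crit.standardized.tolist(),
                "summaries": [
                    {"label": s.label, "mean": s.mean, "sd": s.sd} for s in crit.summaries
                ],
                "correlation": crit.correlation.values.tolist(),
                "variation": crit.variation.tolist(),
                "independence": crit.independence.tolist(),
                "information": crit.information.tolist(),
                "weights": crit.weights.tolist(),
                "convention": crit.convention,
                "magnitude_policy": crit.magnitude_policy,
            },
            "scores": [dataclasses.asdict(s) for s in self.scores],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisReport":
        from .cohort_statistics import CorrelationMatrix
        from .critic import ColumnSummary

        crit = d["critic"]
        data = DataMatrix(
            values=np.array(crit["values"], dtype=float),
            row_ids=tuple(crit["row_ids"]),
            col_labels=tuple(crit["col_labels"]),
        )
        critic_result = CriticResult(
            data=data,
            standardized=np.array(crit["standardized"], dtype=float),
            summaries=tuple(ColumnSummary(**s) for s in crit["summaries"]),
            correlation=CorrelationMatrix(
                values=np.array(crit["correlation"], dtype=float),
                labels=tuple(crit["col_labels"]),
            ),
            variation=np.array(crit["variation"], dtype=float),
            independence=np.array(crit["independence"], dtype=float),
            information=np.array(crit["information"], dtype=float),
            weights=np.array(crit["weights"], dtype=float),
            convention=crit["convention"],
            magnitude_policy=crit["magnitude_policy"],
        )
        return cls(
            config=PipelineConfig.from_dict(d["config"]),
            n_subjects=d["n_subjects"],
            paired_tests={
                name: PairedTestResult(**res) for name, res in d["paired_tests"].items()
            },
            va_improvement_correlations=dict(d["va_improvement_correlations"]),
            critic=critic_result,
            scores=tuple(
                CouplingScore(
                    subject_id=s["subject_id"],
                    ci=s["ci"],
                    normalization=s["normalization"],
                    components=tuple(s["components"]),
                )
                for s in d["scores"]
            ),
            input_hash=d["input_hash"],
            version=d["version"],
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def _hash_records(records: Sequence[ExamRecord]) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: (r.subject_id, r.phase)):
        h.update(repr(r).encode())
    return h.hexdigest()


def run_full_report(
    records: Sequence[ExamRecord], config: PipelineConfig | None = None
) -> AnalysisReport:
    """Run the whole evaluation on a paired cohort of examination records.

    Needs at least 3 paired subjects (the correlation matrix is undefined
    below that). Stage failures propagate as the package's error classes.
    """
    config = config or PipelineConfig()
    diffs = cohort_differences(records)
    if len(diffs) < 3:
        raise ValueError(f"need at least 3 paired subjects, got {len(diffs)}")
    matrix = difference_matrix(diffs)

    tests: dict[str, PairedTestResult] = {
        label: paired_t(matrix.values[:, j]) for j, label in enumerate(matrix.col_labels)
    }
    vpeps = [d.d_vpep for d in diffs]
    if all(v is not None for v in vpeps):
        tests["vertical_pep"] = paired_t(np.asarray(vpeps, dtype=float))

    # Acuity improvement vs the other difference scores: reported r values
    # only — no trend is fitted because none of these pairs tracks linearly.
    full_r = pearson_correlation_matrix(matrix.values, matrix.col_labels)
    va_corr = {
        label: float(full_r.values[0, j])
        for j, label in enumerate(matrix.col_labels)
        if j != 0
    }

    critic_result = run_critic(
        matrix, convention=config.v_convention, magnitude_policy=config.magnitude_policy
    )
    oriented = orient_matrix(matrix.values, matrix.col_labels, config.orientation)
    scores = coupling_index(
        oriented, critic_result.weights, matrix.row_ids, config.ci_normalization
    )
    return AnalysisReport(
        config=config,
        n_subjects=len(diffs),
        paired_tests=tests,
        va_improvement_correlations=va_corr,
        critic=critic_result,
        scores=tuple(scores),
        input_hash=_hash_records(records),
    )
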