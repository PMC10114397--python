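"""Synthetic-cohort generator: determinism, moment/correlation recovery,
grid legality and record-level round trips."""

import numpy as np
import pytest

from visioncouple import (
    CohortSpec,
    cohort_differences,
    generate_cohort,
    generate_differences,
    paired_t,
    run_critic,
)
from visioncouple.critic import critic_weights, independence_coefficients, information_volume
from visioncouple.errors import SpecError
from visioncouple.reference import (
    REFERENCE_CORRELATION,
    REFERENCE_MEANS,
    REFERENCE_SDS,
    REFERENCE_T_MAGNITUDES,
)


class TestSpecValidation:
    def test_zero_sd_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=10, seed=1, target_sds=(0.0, 1.0, 1.0, 1.0))

    def test_tiny_cohort_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=2, seed=1)

    def test_asymmetric_correlation_rejected(self):
        corr = REFERENCE_CORRELATION.copy()
        corr[0, 1] = 0.5
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=10, seed=1, target_correlation=corr)

    def test_non_positive_definite_correlation_rejected(self):
        corr = np.ones((4, 4))  # rank-1, singular
        corr[0, 1] = corr[1, 0] = 0.999999
        with pytest.raises(SpecError, match="positive definite"):
            generate_differences(CohortSpec(n_subjects=10, seed=1, target_correlation=corr))


class TestGenerateDifferences:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_subjects=50, seed=42)
        a = generate_differences(spec).values
        b = generate_differences(spec).values
        assert np.array_equal(a, b)
        c = generate_differences(CohortSpec(n_subjects=50, seed=43)).values
        assert not np.array_equal(a, c)

    def test_large_sample_recovery(self):
        matrix = generate_differences(CohortSpec(n_subjects=10_000, seed=7)).values
        assert np.allclose(matrix.mean(axis=0), REFERENCE_MEANS, atol=0.05)
        assert np.allclose(
            matrix.std(axis=0, ddof=1), REFERENCE_SDS, rtol=0.03
        )
        R = np.corrcoef(matrix, rowvar=False)
        assert np.allclose(R, REFERENCE_CORRELATION, atol=0.03)

    def test_discretized_grids(self):
        matrix = generate_differences(
            CohortSpec(n_subjects=500, seed=9, mode="discretized")
        ).values
        assert np.allclose(matrix[:, 0] * 10, np.round(matrix[:, 0] * 10), atol=1e-9)
        assert np.array_equal(matrix[:, 1], np.round(matrix[:, 1]))
        assert np.array_equal(matrix[:, 3], np.round(matrix[:, 3]))
        assert np.all((matrix[:, 1] >= -7) & (matrix[:, 1] <= 7))
        assert np.all((matrix[:, 3] >= -4) & (matrix[:, 3] <= 4))

    def test_discretization_bias_bounded(self):
        cont = generate_differences(CohortSpec(n_subjects=10_000, seed=5)).values
        disc = generate_differences(
            CohortSpec(n_subjects=10_000, seed=5, mode="discretized")
        ).values
        Rc = np.corrcoef(cont, rowvar=False)
        Rd = np.corrcoef(disc, rowvar=False)
        assert np.max(np.abs(Rd - Rc)) < 0.1

    def test_weights_converge_to_analytic_large_n_limit(self):
        # large-n weights implied directly by the target parameters
        v = np.asarray(REFERENCE_MEANS) / np.asarray(REFERENCE_SDS)
        eta = independence_coefficients(REFERENCE_CORRELATION)
        analytic = critic_weights(information_volume(v, eta, "abs"))
        for seed in (1, 2, 3):
            matrix = generate_differences(CohortSpec(n_subjects=10_000, seed=seed))
            w = run_critic(matrix).weights
            assert np.allclose(w, analytic, atol=0.02)


class TestGenerateCohort:
    def test_requires_discretized_mode(self):
        with pytest.raises(SpecError):
            generate_cohort(CohortSpec(n_subjects=10, seed=1, mode="continuous"))

    def test_roundtrip_recovers_realized_differences(self):
        records, realized = generate_cohort(
            CohortSpec(n_subjects=46, seed=3, mode="discretized")
        )
        assert len(records) == 92
        diffs = cohort_differences(records)
        matrix = np.array([d.as_tuple() for d in diffs])
        assert np.allclose(matrix, realized.values, atol=1e-9)

    def test_records_on_legal_grids(self):
        records, _ = generate_cohort(CohortSpec(n_subjects=60, seed=8, mode="discretized"))
        for r in records:
            assert -0.3 - 1e-9 <= r.va.logmar <= 1.0 + 1e-9
            assert 1 <= r.brbp_right.level <= 8
            assert 1 <= r.brbp_left.level <= 8
            assert 0.0 <= r.pep.horizontal <= 3.0
            assert 0 <= r.stereo.level <= 4
            if r.phase == "pre":
                assert 0.1 - 1e-9 <= r.va.logmar

    def test_deterministic(self):
        spec = CohortSpec(n_subjects=20, seed=77, mode="discretized")
        a, ma = generate_cohort(spec)
        b, mb = generate_cohort(spec)
        assert a == b
        assert np.array_equal(ma.values, mb.values)

    def test_near_zero_difference_spec_keeps_records_stable(self):
        spec = CohortSpec(
            n_subjects=12,
            seed=4,
            mode="discretized",
            target_means=(0.0, 0.0, 0.0, 0.0),
            target_sds=(1e-9, 1e-9, 1e-9, 1e-9),
        )
        records, _ = generate_cohort(spec)
        by_subject = {}
        for r in records:
            by_subject.setdefault(r.subject_id, {})[r.phase] = r
        for phases in by_subject.values():
            pre, post = phases["pre"], phases["post"]
            assert post.va.logmar == pytest.approx(pre.va.logmar, abs=1e-9)
            assert post.brbp_right.level - post.brbp_left.level == pytest.approx(
                pre.brbp_right.level - pre.brbp_left.level
            )
            assert post.pep.horizontal == pytest.approx(pre.pep.horizontal, abs=1e-6)
            assert post.stereo.level == pre.stereo.level

    def test_brbp_t_band_covers_reference_value(self):
        # Monte-Carlo |t| distribution of the interocular-gap difference at
        # n = 46 should straddle the reference cohort's 4.965
        magnitudes = []
        for seed in range(200):
            matrix = generate_differences(
                CohortSpec(n_subjects=46, seed=seed, mode="discretized")
            )
            magnitudes.append(abs(paired_t(matrix.values[:, 1]).t_stat))
        assert min(magnitudes) < REFERENCE_T_MAGNITUDES["brbp"] < max(magnitudes)
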