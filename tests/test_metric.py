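import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemosig import (
    AssessConfig,
    CountMatrix,
    SimulationConfig,
    assess,
    simulate_counts,
)
from hemosig.metric import (
    CAUTION,
    CLEAR,
    SignatureCoverageError,
    UndefinedMetricError,
    classify,
    geometric_mean,
    haemolysis_metric,
    partition_signature,
    proxy_delta_cq,
)
from hemosig.normalize import NormalizedMatrix, log2_cpm


def _norm(values, mirna_ids, sample_ids=None, detected=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    detected = np.ones_like(values, dtype=bool) if detected is None else detected
    return NormalizedMatrix(
        list(mirna_ids),
        list(sample_ids),
        values,
        np.ones(values.shape[1]),
        np.full(values.shape[1], 1e6),
        detected,
    )


def _signature_matrix(n_background=169, bundled=None):
    """Normalized matrix holding all 20 signature miRNAs plus a background."""
    ids = list(bundled.mirna_ids) + [f"miR-bg{i}" for i in range(n_background)]
    rng = np.random.default_rng(5)
    values = rng.uniform(6, 14, size=(len(ids), 3))
    return _norm(values, ids)


class TestPartition:
    def test_full_partition_sizes(self, bundled_signature):
        norm = _signature_matrix(169, bundled_signature)
        part = partition_signature(norm, bundled_signature)
        assert part.p1 == 20
        assert part.p2 == 169

    def test_condition_exclusion_reduces_signature(self, bundled_signature):
        norm = _signature_matrix(169, bundled_signature)
        exclude = set(bundled_signature.condition_associated_ids)
        part = partition_signature(norm, bundled_signature, exclude)
        assert part.p1 == 10
        assert part.p2 == 169
        assert set(part.excluded_ids) == exclude

    def test_exclusion_also_prunes_background(self, bundled_signature):
        norm = _signature_matrix(169, bundled_signature)
        part = partition_signature(norm, bundled_signature, {"miR-bg0", "miR-bg1"})
        assert part.p1 == 20
        assert part.p2 == 167

    def test_signature_only_mode_keeps_background(self, bundled_signature):
        norm = _signature_matrix(169, bundled_signature)
        part = partition_signature(
            norm, bundled_signature, {"miR-451a", "miR-bg0"}, exclude_mode="signature_only"
        )
        assert part.p1 == 19
        assert part.p2 == 169  # background untouched in this mode

    def test_excluding_whole_signature_errors(self, bundled_signature):
        norm = _signature_matrix(169, bundled_signature)
        with pytest.raises(SignatureCoverageError, match="coverage too low"):
            partition_signature(norm, bundled_signature, set(bundled_signature.mirna_ids))

    def test_missing_signature_mirnas_warn(self, bundled_signature, caplog):
        ids = list(bundled_signature.mirna_ids[:8]) + [f"miR-bg{i}" for i in range(30)]
        norm = _norm(np.full((len(ids), 2), 8.0), ids)
        with caplog.at_level("WARNING"):
            part = partition_signature(norm, bundled_signature)
        assert part.p1 == 8
        assert any("absent" in rec.message for rec in caplog.records)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected", [([4, 4, 4], 4.0), ([2, 8], 4.0), ([9.0], 9.0)]
    )
    def test_examples(self, values, expected):
        assert geometric_mean(np.array(values, dtype=float)) == pytest.approx(expected)

    @given(
        st.lists(st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False), min_size=1, max_size=40)
    )
    def test_log_space_identity(self, values):
        arr = np.array(values)
        expected = np.exp(np.mean(np.log(arr)))
        assert geometric_mean(arr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [[], [0.0], [-1.0, 2.0], [np.nan]])
    def test_rejects_nonpositive_or_empty(self, bad):
        with pytest.raises(ValueError):
            geometric_mean(np.array(bad, dtype=float))


class TestHaemolysisMetric:
    def test_constant_sets(self):
        norm = _norm(np.array([[8.0], [8.0], [6.0], [6.0]]), ["miR-a", "miR-b", "miR-c", "miR-d"])
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a", "miR-b"], ["miR-c", "miR-d"])
        value, p1, p2 = haemolysis_metric(norm, part, "s0")
        assert value == pytest.approx(2.0)
        assert (p1, p2) == (2, 2)

    def test_identical_sets_give_zero(self):
        norm = _norm(np.full((4, 1), 7.0), ["miR-a", "miR-b", "miR-c", "miR-d"])
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a", "miR-b"], ["miR-c", "miR-d"])
        assert haemolysis_metric(norm, part, "s0")[0] == pytest.approx(0.0)

    def test_hand_worked_value(self):
        # GM(4, 9) - GM(2, 8) = 6 - 4 = 2
        norm = _norm(np.array([[4.0], [9.0], [2.0], [8.0]]), ["miR-a", "miR-b", "miR-c", "miR-d"])
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a", "miR-b"], ["miR-c", "miR-d"])
        assert haemolysis_metric(norm, part, "s0")[0] == pytest.approx(2.0)

    def test_undetected_cells_are_dropped_and_counted(self):
        detected = np.array([[True], [False], [True], [True]])
        norm = _norm(
            np.array([[4.0], [9.0], [2.0], [8.0]]),
            ["miR-a", "miR-b", "miR-c", "miR-d"],
            detected=detected,
        )
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a", "miR-b"], ["miR-c", "miR-d"])
        value, p1, p2 = haemolysis_metric(norm, part, "s0")
        assert value == pytest.approx(4.0 - 4.0)
        assert (p1, p2) == (1, 2)

    def test_no_detected_signature_is_undefined(self):
        detected = np.array([[False], [True]])
        norm = _norm(np.array([[4.0], [2.0]]), ["miR-a", "miR-c"], detected=detected)
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a"], ["miR-c"])
        with pytest.raises(UndefinedMetricError):
            haemolysis_metric(norm, part, "s0")

    def test_mean_mode_is_arithmetic_difference(self):
        norm = _norm(np.array([[4.0], [9.0], [2.0], [8.0]]), ["miR-a", "miR-b", "miR-c", "miR-d"])
        from hemosig.metric import SignaturePartition

        part = SignaturePartition(["miR-a", "miR-b"], ["miR-c", "miR-d"])
        value, _, _ = haemolysis_metric(norm, part, "s0", metric_mode="mean_log2cpm")
        assert value == pytest.approx(6.5 - 5.0)


class TestClassify:
    @pytest.mark.parametrize(
        "value, expected",
        [(1.9, CAUTION), (1.89, CLEAR), (-0.5, CLEAR), (5.0, CAUTION)],
    )
    def test_boundary(self, value, expected):
        assert classify(value) == expected

    def test_custom_threshold(self):
        assert classify(1.0, threshold=0.8) == CAUTION

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))


class TestProxyDeltaCq:
    def test_subtraction_orientation(self):
        norm = _norm(np.array([[13.0], [10.0]]), ["miR-451a", "miR-23a-3p"])
        assert proxy_delta_cq(norm, "s0") == pytest.approx(3.0)

    def test_equal_markers_give_zero(self):
        norm = _norm(np.array([[9.0], [9.0]]), ["miR-451a", "miR-23a-3p"])
        assert proxy_delta_cq(norm, "s0") == pytest.approx(0.0)

    def test_missing_marker_not_available(self):
        norm = _norm(np.array([[13.0]]), ["miR-451a"])
        assert np.isnan(proxy_delta_cq(norm, "s0"))

    def test_undetected_marker_not_available(self):
        detected = np.array([[True], [False]])
        norm = _norm(np.array([[13.0], [10.0]]), ["miR-451a", "miR-23a-3p"], detected=detected)
        assert np.isnan(proxy_delta_cq(norm, "s0"))


class TestAssess:
    def test_contaminated_sample_has_max_metric_and_caution(self, bundled_signature):
        fractions = np.zeros(8)
        fractions[3] = 0.6
        cfg = SimulationConfig(n_samples=8, contamination_fractions=fractions, seed=7)
        matrix, _ = simulate_counts(cfg)
        report = assess(matrix, bundled_signature)
        assert int(np.argmax(report.haemolysis_metric)) == 3
        assert report.classification[3] == CAUTION

    def test_null_cohort_all_clear(self, clean_cohort, bundled_signature):
        matrix, _ = clean_cohort
        report = assess(matrix, bundled_signature)
        assert all(c == CLEAR for c in report.classification)

    def test_same_distribution_metrics_near_zero(self, bundled_signature):
        # no RBC enrichment and no baseline elevation: signature and
        # background counts come from one distribution
        cfg = SimulationConfig(
            n_samples=10, seed=3, log2_enrichment=0.0, enriched_baseline_log2_boost=0.0
        )
        matrix, _ = simulate_counts(cfg)
        report = assess(matrix, bundled_signature)
        assert np.all(np.abs(report.haemolysis_metric) < 0.5)
        assert all(c == CLEAR for c in report.classification)

    def test_identical_samples_get_identical_metrics(self, bundled_signature):
        cfg = SimulationConfig(n_samples=4, contamination_fractions=np.zeros(4), seed=2)
        matrix, _ = simulate_counts(cfg)
        dup = CountMatrix(
            list(matrix.mirna_ids),
            ["a", "b"] + matrix.sample_ids[2:],
            np.column_stack([matrix.counts[:, 0], matrix.counts[:, 0], matrix.counts[:, 2:]]),
        )
        report = assess(dup, bundled_signature)
        assert report.haemolysis_metric[0] == pytest.approx(report.haemolysis_metric[1], abs=1e-12)

    def test_scale_invariance_per_sample(self, bundled_signature):
        cfg = SimulationConfig(n_samples=4, seed=9)
        matrix, _ = simulate_counts(cfg)
        counts = matrix.counts.copy()
        counts[:, 1] *= 3
        scaled = CountMatrix(list(matrix.mirna_ids), list(matrix.sample_ids), counts)
        config = AssessConfig(min_count=0, prior=0.0)
        a = assess(matrix, bundled_signature, config=config)
        b = assess(scaled, bundled_signature, config=config)
        # CPM is exactly scale-invariant; TMM precision weights depend on the
        # absolute library size, so equality holds to weighting precision.
        np.testing.assert_allclose(a.haemolysis_metric, b.haemolysis_metric, atol=1e-4)

    def test_excluded_rows_equal_deleted_rows(self, bundled_signature):
        norm = _signature_matrix(30, bundled_signature)
        exclude = {"miR-451a", "miR-bg3", "miR-bg7"}
        part = partition_signature(norm, bundled_signature, exclude)
        with_exclusion = haemolysis_metric(norm, part, "s1")[0]
        keep = [i for i, m in enumerate(norm.mirna_ids) if m not in exclude]
        pruned = _norm(
            norm.log2cpm[keep, :], [norm.mirna_ids[i] for i in keep], norm.sample_ids
        )
        part2 = partition_signature(pruned, bundled_signature)
        deleted = haemolysis_metric(pruned, part2, "s1")[0]
        assert with_exclusion == pytest.approx(deleted, abs=1e-12)

    def test_monotone_under_signature_enrichment(self, bundled_signature):
        cfg = SimulationConfig(n_samples=3, contamination_fractions=np.zeros(3), seed=4)
        matrix, _ = simulate_counts(cfg)
        norm = log2_cpm(matrix)
        part = partition_signature(norm, bundled_signature)
        base = haemolysis_metric(norm, part, matrix.sample_ids[0])[0]
        sig_rows = [matrix.mirna_ids.index(m) for m in part.signature_ids]
        boosted_counts = matrix.counts.copy()
        boosted_counts[sig_rows, 0] += 50_000
        boosted = CountMatrix(list(matrix.mirna_ids), list(matrix.sample_ids), boosted_counts)
        after = haemolysis_metric(log2_cpm(boosted), part, matrix.sample_ids[0])[0]
        assert after >= base

    def test_report_carries_qc_fields(self, simulated_cohort, bundled_signature):
        matrix, _ = simulated_cohort
        report = assess(matrix, bundled_signature)
        assert report.sample_ids == matrix.sample_ids
        assert np.array_equal(report.library_size, matrix.library_sizes)
        assert np.all(report.n_signature_used <= 20)
        assert np.all(report.n_background_used >= 1)
        floored = np.where(matrix.counts < 5, 0, matrix.counts)
        assert np.array_equal(report.n_detected_mirnas, (floored > 0).sum(axis=0))
        # classification consistent with threshold everywhere
        for value, label in zip(report.haemolysis_metric, report.classification):
            assert label == (CAUTION if value >= report.threshold else CLEAR)
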