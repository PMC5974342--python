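"""Four-criterion PCR-Stop analysis engine."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcrstop import (
    AssayProfile,
    BatchSummary,
    POOR_ASSAY_PROFILE,
    PCRStopDesign,
    compile_report,
    criterion_negatives,
    criterion_resolution,
    criterion_rsd,
    estimate_early_efficiency,
    export_ordered_curves,
    simulate_pcr_stop,
    summarize_batches,
)
from pcrstop.analysis import _verdict


def summaries_from_means(means, rsds=None):
    rsds = rsds or [0.0] * len(means)
    out = []
    for k, (m, r) in enumerate(zip(means, rsds)):
        out.append(
            BatchSummary(prerun_cycles=k, n_wells=8, n_negative=0,
                         mean_copies=m, sd_copies=m * r / 100, rsd_percent=r)
        )
    return out


class TestSummarizeBatches:
    def test_constant_batch_has_zero_rsd(self, plate_builder):
        plate = plate_builder({0: [10] * 8, 1: [20] * 8})
        s = summarize_batches(plate)
        assert s[0].mean_copies == 10 and s[0].rsd_percent == 0.0

    def test_all_negative_batch_is_undefined(self, plate_builder):
        plate = plate_builder({0: [None] * 8, 1: [20] * 8})
        s = summarize_batches(plate)
        assert s[0].n_negative == 8
        assert s[0].mean_copies is None and s[0].rsd_percent is None

    def test_hand_computed_sample_statistics(self, plate_builder):
        # n-1 denominator: SS = 10 over 7 dof
        plate = plate_builder({0: [8, 9, 10, 10, 10, 10, 11, 12], 1: [20] * 8})
        s = summarize_batches(plate, negatives_policy="exclude")[0]
        assert s.mean_copies == pytest.approx(10.0)
        assert s.sd_copies == pytest.approx(math.sqrt(10 / 7), rel=1e-12)
        assert s.rsd_percent == pytest.approx(11.95, abs=0.01)

    def test_as_zero_policy_counts_negatives_as_zero_copies(self, plate_builder):
        plate = plate_builder({0: [10, 10, None, None], 1: [20] * 4})
        excl = summarize_batches(plate, negatives_policy="exclude")[0]
        zero = summarize_batches(plate, negatives_policy="as_zero")[0]
        assert excl.mean_copies == 10.0
        assert zero.mean_copies == 5.0

    def test_unknown_policy_rejected(self, plate_builder):
        plate = plate_builder({0: [1, 2]})
        with pytest.raises(ValueError):
            summarize_batches(plate, negatives_policy="drop")

    def test_duplicated_batch_yields_identical_statistics(self, plate_builder):
        values = [8.0, 9.5, 10.0, 10.2, 10.8, 11.0, 12.1, 13.0]
        plate = plate_builder({0: values, 1: values})
        a, b = summarize_batches(plate)
        assert a.mean_copies == b.mean_copies
        assert a.sd_copies == b.sd_copies


class TestEarlyEfficiency:
    def test_ideal_doubling_series(self):
        eff, r2 = estimate_early_efficiency(summaries_from_means([10, 20, 40, 80, 160, 320]))
        assert eff == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_means_give_zero_efficiency(self):
        eff, r2 = estimate_early_efficiency(summaries_from_means([50, 50, 50, 50]))
        assert eff == pytest.approx(0.0, abs=1e-12)
        assert r2 == 1.0

    def test_realistic_well_performing_series(self):
        means = [10 * 1.937**k for k in range(6)]
        eff, r2 = estimate_early_efficiency(summaries_from_means(means))
        assert eff == pytest.approx(0.937, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @given(
        e=st.floats(0.01, 1.2),
        x0=st.sampled_from([5.0, 10.0, 100.0]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_exact_on_noiseless_geometric_series(self, e, x0):
        means = [x0 * (1 + e) ** k for k in range(6)]
        eff, r2 = estimate_early_efficiency(summaries_from_means(means))
        assert eff == pytest.approx(e, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_requires_three_usable_batches(self):
        with pytest.raises(ValueError):
            estimate_early_efficiency(summaries_from_means([10, 20]))

    def test_skips_undefined_batches(self):
        s = summaries_from_means([10, 20, 40, 80])
        s.append(BatchSummary(4, 8, 8, None, None, None))
        eff, _ = estimate_early_efficiency(s)
        assert eff == pytest.approx(1.0, abs=1e-12)


class TestCriterionRsd:
    def test_perfect_assay_passes_at_zero(self):
        res = criterion_rsd(summaries_from_means([10, 20, 40], rsds=[0, 0, 0]))
        assert res.passed and res.statistics["average_rsd"] == 0.0

    def test_marginal_average_fails_default_threshold(self):
        res = criterion_rsd(
            summaries_from_means([1] * 6, rsds=[20, 16, 17, 24, 31, 25])
        )
        assert res.statistics["average_rsd"] == pytest.approx(22.1667, abs=1e-3)
        assert not res.passed

    def test_grossly_irregular_assay_fails(self):
        res = criterion_rsd(
            summaries_from_means([1] * 6, rsds=[63, 282, 103, 174, 720, 185])
        )
        assert not res.passed

    def test_single_batch_spike_fails_even_with_low_average(self):
        # average under threshold but one batch above 2x threshold
        res = criterion_rsd(summaries_from_means([1] * 6, rsds=[5, 5, 5, 5, 5, 45]))
        assert res.statistics["average_rsd"] < 20
        assert not res.passed


def brute_force_inversions(lower, upper):
    """Independent oracle: plain-Python rank-by-rank comparison."""
    a = sorted(float(v) for v in lower)
    b = sorted(float(v) for v in upper)
    inv = 0
    for rank in range(min(len(a), len(b))):
        if a[rank] >= b[rank]:
            inv += 1
    return inv


class TestCriterionResolution:
    def test_separated_constants_pass(self, plate_builder):
        plate = plate_builder({0: [10] * 8, 1: [20] * 8})
        res = criterion_resolution(plate)
        assert res.passed and res.statistics["inversions"] == 0

    def test_single_outlier_creates_one_inversion_and_overlap(self, plate_builder):
        plate = plate_builder({0: [10, 10, 10, 10, 10, 10, 10, 25], 1: [20] * 8})
        res = criterion_resolution(plate)
        assert res.statistics["inversions"] == 1
        assert res.statistics["interval_overlaps"] == [(0, 1)]
        assert not res.passed

    def test_theory_plate_fully_separated(self, theory_plate):
        res = criterion_resolution(theory_plate)
        assert res.passed
        assert res.statistics["inversions"] == 0
        assert res.statistics["interval_overlaps"] == []

    def test_all_negative_batch_skipped_not_fatal(self, plate_builder):
        plate = plate_builder({0: [10] * 4, 1: [None] * 4, 2: [40] * 4})
        res = criterion_resolution(plate)
        assert res.statistics["skipped_batches"] == [1]
        assert res.passed

    def test_matches_brute_force_oracle_on_random_instances(self, plate_builder):
        rng = np.random.default_rng(2018)
        for _ in range(300):
            n_batches = int(rng.integers(2, 5))
            batches = {
                k: rng.integers(1, 40, size=int(rng.integers(2, 9))).astype(float).tolist()
                for k in range(n_batches)
            }
            plate = plate_builder(batches)
            expected = sum(
                brute_force_inversions(batches[k], batches[k + 1])
                for k in range(n_batches - 1)
            )
            assert criterion_resolution(plate).statistics["inversions"] == expected


class TestCriterionNegatives:
    def test_no_negatives_passes(self, plate_builder):
        plate = plate_builder({0: [10] * 8, 1: [20] * 8})
        assert criterion_negatives(plate).passed

    def test_negatives_in_most_batches_fail(self, plate_builder):
        batches = {k: [None] + [10.0 * 2**k] * 7 for k in range(5)}
        batches[5] = [320.0] * 8
        res = criterion_negatives(plate_builder(batches))
        assert not res.passed
        assert res.statistics["batches_with_negatives"] == 5

    def test_binomial_rule_flags_few_negatives_at_high_template(self, plate_builder):
        # with lambda=10 the chance of even one template-zero well is ~0.2%
        batches = {k: [10.0 * 2**k] * 8 for k in range(6)}
        batches[0] = [None, None, None] + [10.0] * 5
        res = criterion_negatives(plate_builder(batches), expected_template_mean=10)
        assert not res.passed
        assert res.statistics["allowed_negatives_99pct"] == 0


class TestVerdictAndReport:
    @pytest.mark.parametrize("flags", list(itertools.product([True, False], repeat=4)))
    def test_verdict_is_pure_function_of_flags(self, flags):
        passes = dict(zip("I II III IV".split(), flags))
        verdict = _verdict(passes)
        if not passes["IV"]:
            assert verdict == "failed"
        elif all(flags):
            assert verdict == "validated"
        else:
            assert verdict == "limited"

    def test_theory_plate_is_validated(self, theory_plate):
        report = compile_report(theory_plate)
        assert report.verdict == "validated"
        assert report.efficiency_hat == pytest.approx(1.0, abs=1e-9)
        assert report.efficiency_r2 == pytest.approx(1.0, abs=1e-12)
        assert all(c.passed for c in report.criteria)

    def test_all_negative_plate_fails(self, plate_builder):
        plate = plate_builder({k: [None] * 8 for k in range(6)})
        report = compile_report(plate)
        assert report.verdict == "failed"
        assert "higher initial DNA quantity" in report.recommendation

    def test_poor_assay_fails_in_nearly_all_replicates(self):
        design = PCRStopDesign(initial_template=10)
        failed = sum(
            compile_report(
                simulate_pcr_stop(design, POOR_ASSAY_PROFILE, seed=seed),
                expected_template_mean=10,
            ).verdict
            == "failed"
            for seed in range(200)
        )
        assert failed >= 190  # >= 95% of 200 replicates

    def test_parameter_recovery_median_efficiency(self):
        # deeper 500-replicate version lives in the acceptance suite
        design = PCRStopDesign(initial_template=100)
        profile = AssayProfile(duplication_prob=0.94, quantification_cv=0.2)
        effs = [
            estimate_early_efficiency(
                summarize_batches(simulate_pcr_stop(design, profile, seed=seed))
            )[0]
            for seed in range(100)
        ]
        assert abs(float(np.median(effs)) - 0.94) < 0.05


class TestOrderedCurves:
    def test_sorting_and_rank_assignment(self, plate_builder):
        plate = plate_builder({0: [3, 1, 2]})
        table = export_ordered_curves(plate)
        assert table["rank"].tolist() == [1, 2, 3]
        assert table["observed_copies"].tolist() == [1.0, 2.0, 3.0]

    def test_negatives_come_first_on_axis(self, plate_builder):
        plate = plate_builder({0: [5, None, 4]})
        table = export_ordered_curves(plate)
        assert bool(table.iloc[0]["negative"])
        assert table["observed_copies"].tolist()[1:] == [4.0, 5.0]

    def test_theory_plate_gives_six_flat_curves(self, theory_plate):
        table = export_ordered_curves(theory_plate)
        for prerun, expected in zip(range(6), [10, 20, 40, 80, 160, 320]):
            vals = table[table["batch_prerun"] == prerun]["observed_copies"]
            assert (vals == expected).all()
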