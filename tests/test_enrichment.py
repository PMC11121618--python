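"""Random control sampling, proportion statistics, and sample labelling."""

import numpy as np
import pytest

from g4mm.enrichment import (
    ContingencyTable,
    Context,
    SampleLabel,
    chi_square_independence,
    evaluate_sample,
    evaluate_sample_categories,
    sample_random_windows,
    summarize_groups,
    two_proportion_z,
    wilson_interval,
)
from g4mm.g4scan import G4Category
from g4mm.genome_io import GenomicInterval


# ---------------------------------------------------------------------------
# Control sampling


class TestSampleRandomWindows:
    @pytest.fixture
    def reference(self, rng):
        return {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}

    def test_seeded_determinism(self, reference):
        panel = [GenomicInterval("chr1", 0, 1000)]
        a = sample_random_windows(reference, panel, n=50, rng=7)
        b = sample_random_windows(reference, panel, n=50, rng=7)
        assert [(w.interval.start, w.seq) for w in a] == [
            (w.interval.start, w.seq) for w in b
        ]

    def test_anchors_inside_panel(self, reference):
        panel = [GenomicInterval("chr1", 100, 400)]
        windows = sample_random_windows(reference, panel, n=200, flank=70, rng=1)
        for w in windows:
            anchor = w.interval.start + (w.flank - w.clipped_left)
            assert 100 <= anchor < 400

    def test_length_proportional_interval_choice(self, reference):
        panel = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1000, 1900)]
        windows = sample_random_windows(reference, panel, n=20_000, flank=0, rng=3)
        in_small = sum(w.interval.start < 500 for w in windows)
        # binomial(20000, 0.1): mean 2000, sd ~42; allow 5 sigma
        assert abs(in_small - 2000) < 5 * 42

    def test_empty_panel_and_bad_n(self, reference):
        with pytest.raises(ValueError):
            sample_random_windows(reference, [], n=10)
        with pytest.raises(ValueError):
            sample_random_windows(reference, [GenomicInterval("chr1", 0, 10)], n=0)


# ---------------------------------------------------------------------------
# Statistics


class TestWilson:
    def test_boundaries_exact(self):
        assert wilson_interval(0, 50)[0] == 0.0
        assert wilson_interval(50, 50)[1] == 1.0

    def test_closed_form_value(self):
        lo, hi = wilson_interval(50, 100, 0.95)
        assert lo == pytest.approx(0.4038, abs=5e-5)
        assert hi == pytest.approx(0.5962, abs=5e-5)

    def test_contains_point_estimate_exhaustive(self):
        for n in range(1, 201):
            for k in range(0, n + 1):
                lo, hi = wilson_interval(k, n)
                assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 4)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p, dof = chi_square_independence(ContingencyTable(10, 20, 10, 20))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and dof == 1

    def test_hand_computed_value(self):
        stat, p, _ = chi_square_independence(ContingencyTable(30, 100, 10, 100))
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(4.07e-4, rel=1e-2)

    def test_yates_continuity(self):
        stat, _, _ = chi_square_independence(
            ContingencyTable(30, 100, 10, 100), continuity=True
        )
        assert stat == pytest.approx(11.28125)

    def test_zero_marginal_degenerate(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence(ContingencyTable(0, 100, 0, 2000))


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p, degenerate = two_proportion_z(10, 100, 10, 100)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0) and not degenerate

    def test_hand_computed_value(self):
        z, p, _ = two_proportion_z(20, 100, 10, 100)
        assert z == pytest.approx(1.980, abs=1e-3)
        assert p == pytest.approx(0.0477, abs=1e-3)

    def test_sign_convention(self):
        assert two_proportion_z(30, 100, 10, 100)[0] > 0
        assert two_proportion_z(10, 100, 30, 100)[0] < 0

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(0, 100, 0, 2000) == (0.0, 1.0, True)
        assert two_proportion_z(100, 100, 2000, 2000) == (0.0, 1.0, True)

    def test_z_squared_equals_chi_square_exhaustive_small_tables(self):
        """z^2 = chi^2 (no continuity) on every non-degenerate 2x2, n<=12."""
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for k1 in range(0, n1 + 1):
                    for k2 in range(0, n2 + 1):
                        pooled = (k1 + k2) / (n1 + n2)
                        if pooled in (0.0, 1.0):
                            continue
                        z, zp, _ = two_proportion_z(k1, n1, k2, n2)
                        chi2, cp, _ = chi_square_independence(
                            ContingencyTable(k1, n1, k2, n2)
                        )
                        assert z * z == pytest.approx(chi2, rel=1e-9, abs=1e-12)
                        assert zp == pytest.approx(cp, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# Sample evaluation and group summary


def _cats(n_strong, n_weak, n_none):
    return (
        [G4Category.STRONG] * n_strong
        + [G4Category.WEAK] * n_weak
        + [G4Category.NONE] * n_none
    )


class TestEvaluateSample:
    def test_clear_strong_enrichment(self):
        results, label = evaluate_sample_categories(
            _cats(40, 0, 23), _cats(300, 0, 1700)
        )
        assert label is SampleLabel.G4_STRONG
        strong = next(r for r in results if r.context is Context.STRONG)
        assert strong.significant_enrichment
        assert strong.z_p < 1e-6 and strong.chi2_p < 1e-6

    def test_matched_proportions_not_labelled(self):
        results, label = evaluate_sample_categories(
            _cats(15, 0, 85), _cats(300, 0, 1700)
        )
        assert label is SampleLabel.NONE

    def test_depletion_is_not_enrichment(self):
        _, label = evaluate_sample_categories(_cats(1, 0, 99), _cats(400, 0, 1600))
        assert label is SampleLabel.NONE

    def test_combined_weak_plus_strong_label(self):
        # strong matched to control, but weak wildly elevated
        _, label = evaluate_sample_categories(
            _cats(15, 60, 25), _cats(300, 400, 1300)
        )
        assert label is SampleLabel.G4_WEAK_PLUS_STRONG

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_sample([], [], 0.05)

    def test_wilson_ci_brackets_proportions(self):
        results, _ = evaluate_sample_categories(_cats(10, 5, 35), _cats(100, 50, 350))
        for r in results:
            assert r.wilson_tumor[0] <= r.prop_tumor <= r.wilson_tumor[1]
            assert r.wilson_control[0] <= r.prop_control <= r.wilson_control[1]


class TestSummarizeGroups:
    def test_study_scale_group_means(self):
        labels = {
            "S12": SampleLabel.G4_STRONG,
            "P23": SampleLabel.G4_STRONG,
            "P37": SampleLabel.G4_STRONG,
            "S7": SampleLabel.NONE,
            "P1": SampleLabel.NONE,
            "P14": SampleLabel.NONE,
            "P20": SampleLabel.NONE,
            "P22": SampleLabel.NONE,
            "P30": SampleLabel.NONE,
            "P34": SampleLabel.NONE,
            "P48": SampleLabel.G4_WEAK_PLUS_STRONG,
        }
        counts = {
            "S12": 63, "P23": 119, "P37": 82,
            "S7": 115, "P1": 87, "P14": 234, "P20": 182, "P22": 191,
            "P30": 662, "P34": 267, "P48": 227,
        }
        df = summarize_groups(labels, counts).set_index("group")
        assert df.loc["G4_strong_enriched", "mean_mutations"] == 88.0
        assert df.loc["without_G4_strong_enrichment", "mean_mutations"] == 245.625
        assert df.loc["without_G4_strong_enrichment", "n_samples"] == 8

    def test_single_sample_group(self):
        df = summarize_groups({"A": SampleLabel.G4_STRONG}, {"A": 42}).set_index("group")
        assert df.loc["G4_strong_enriched", "mean_mutations"] == 42.0
        assert np.isnan(df.loc["without_G4_strong_enrichment", "mean_mutations"])

    def test_label_count_mismatch(self):
        with pytest.raises(ValueError):
            summarize_groups({"A": SampleLabel.NONE}, {"B": 1})
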