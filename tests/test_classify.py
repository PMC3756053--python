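import math

import pytest

from bsclones.amplicons import AmpliconSpec
from bsclones.bisulfite import Call
from bsclones.classify import (
    SCHEME_LABELS,
    aggregate_line1,
    classify_ctcf6,
    classify_dazl,
    classify_h19,
    summarize_patient,
)

M, U, X, K = Call.METHYLATED, Call.UNMETHYLATED, Call.MISSING, Call.MASKED


def h19_calls(n_unmeth, n_inf=17, n_missing=0, masked_at=7):
    """An 18-CpG call vector with the polymorphic ordinal masked."""
    states = [U] * n_unmeth + [M] * (n_inf - n_unmeth) + [X] * n_missing
    assert len(states) == 17
    states.insert(masked_at - 1, K)
    return tuple(states)


class TestH19Scheme:
    @pytest.mark.parametrize(
        "n_unmeth,label",
        [
            (0, "complete_methylation"),
            (1, "mild_hypomethylation"),
            (8, "mild_hypomethylation"),   # 8/17 < 0.5
            (9, "severe_hypomethylation"),  # 9/17 >= 0.5
            (16, "severe_hypomethylation"),
            (17, "complete_unmethylation"),
        ],
    )
    def test_bins(self, n_unmeth, label):
        cat = classify_h19(h19_calls(n_unmeth))
        assert cat.label == label
        assert cat.n_informative == 17
        assert cat.n_unmethylated == n_unmeth

    def test_missing_excluded_from_denominator(self):
        cat = classify_h19(h19_calls(4, n_inf=8, n_missing=9))
        assert cat.n_informative == 8
        assert cat.label == "severe_hypomethylation"  # 4/8 = 0.5, left-closed

    def test_no_informative_cpgs_excluded(self):
        assert classify_h19((K, X, X)) is None

    def test_half_fraction_unreachable_at_full_length(self):
        # 17 informative CpGs cannot realize f = 0.5 exactly
        assert all(u / 17 != 0.5 for u in range(18))

    def test_severe_plus_complete_equals_majority_unmethylated(self):
        # the ">50% unmethylated" clone set is exactly these two bins
        for u in range(18):
            cat = classify_h19(h19_calls(u))
            majority = u / 17 >= 0.5
            assert (
                cat.label in ("severe_hypomethylation", "complete_unmethylation")
            ) == majority


class TestCtcf6Scheme:
    def window_calls(self, n_unmeth, missing=0):
        # ordinals 4-8 with 7 masked: 4 informative window CpGs
        inside = [U] * n_unmeth + [M] * (4 - n_unmeth - missing) + [X] * missing
        calls = [M, M, M] + inside[:3] + [K] + inside[3:] + [M] * 10
        return tuple(calls)

    @pytest.mark.parametrize(
        "n_unmeth,label",
        [
            (0, "complete_methylation"),
            (1, "hypomethylation"),
            (2, "hypomethylation"),
            (3, "hypomethylation"),
            (4, "complete_unmethylation"),
        ],
    )
    def test_count_based_bins(self, n_unmeth, label):
        cat = classify_ctcf6(self.window_calls(n_unmeth))
        assert cat.label == label
        assert cat.n_informative == 4

    def test_missing_window_cpg_excludes_clone(self):
        assert classify_ctcf6(self.window_calls(1, missing=1)) is None

    def test_outside_window_ignored(self):
        calls = [U] * 3 + [M, M, M] + [K] + [M] + [U] * 10
        cat = classify_ctcf6(tuple(calls))
        assert cat.label == "complete_methylation"


class TestDazlScheme:
    def dazl_calls(self, n_meth, n_inf=31):
        return tuple([M] * n_meth + [U] * (n_inf - n_meth))

    @pytest.mark.parametrize(
        "n_meth,label",
        [
            (0, "complete_unmethylation"),
            (1, "mild_hypermethylation"),
            (6, "mild_hypermethylation"),    # 6/31 < 0.2
            (7, "moderate_hypermethylation"),  # 7/31 >= 0.2
            (24, "moderate_hypermethylation"),  # 24/31 < 0.8
            (25, "severe_hypermethylation"),   # 25/31 >= 0.8
            (31, "severe_hypermethylation"),
        ],
    )
    def test_bins(self, n_meth, label):
        assert classify_dazl(self.dazl_calls(n_meth)).label == label

    def test_boundaries_on_truncated_clones(self):
        # 0.2 and 0.8 are unreachable at 31 CpGs but reachable at 5:
        assert classify_dazl(self.dazl_calls(1, 5)).label == "moderate_hypermethylation"
        assert classify_dazl(self.dazl_calls(4, 5)).label == "severe_hypermethylation"
        assert all(m / 31 != 0.2 and m / 31 != 0.8 for m in range(32))


class TestBinPartition:
    def test_every_count_maps_to_exactly_one_label(self):
        # exhaustive over informative counts up to 40
        for n in range(1, 41):
            for u in range(n + 1):
                calls = tuple([U] * u + [M] * (n - u))
                h = classify_h19(calls)
                d = classify_dazl(calls)
                assert h.label in SCHEME_LABELS["H19_DMR"]
                assert d.label in SCHEME_LABELS["DAZL"]
                assert h.n_unmethylated + h.n_methylated == h.n_informative == n


class TestSummaries:
    def _clones(self, labels_counts, spec):
        clones = []
        for n_unmeth, n in labels_counts:
            for _ in range(n):
                calls = h19_calls(n_unmeth)
                clones.append((calls, {"H19_DMR": classify_h19(calls)}))
        return clones

    def test_percentages(self, h19):
        clones = self._clones([(0, 19), (2, 1)], h19)
        s = summarize_patient(clones, "P1", "NZ", h19, schemes=["H19_DMR"])
        pct = s.category_percentages["H19_DMR"]
        assert pct["complete_methylation"] == pytest.approx(95.0)
        assert pct["mild_hypomethylation"] == pytest.approx(5.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_single_clone_is_100_percent(self, h19):
        s = summarize_patient(self._clones([(17, 1)], h19), "P1", "OZ", h19, schemes=["H19_DMR"])
        assert s.category_percentages["H19_DMR"]["complete_unmethylation"] == 100.0

    def test_empty_patient_flagged(self, h19):
        s = summarize_patient([], "P9", "NZ", h19, schemes=["H19_DMR"])
        assert s.empty and s.n_clones_pass == 0

    def test_per_cpg_fractions(self, h19):
        clones = self._clones([(0, 3), (17, 1)], h19)
        s = summarize_patient(clones, "P1", "OZ", h19, schemes=["H19_DMR"])
        assert len(s.per_cpg_methylation_fraction) == 17
        assert all(f == pytest.approx(0.75) for f in s.per_cpg_methylation_fraction)

    def test_mixture_recovered_within_sampling_error(self, h19, rng):
        # 200 clones drawn from a 4-bin mixture: percentages within 3 SE
        from bsclones.simulate import sample_pattern
        probs = [0.6, 0.3, 0.05, 0.05]
        labels = SCHEME_LABELS["H19_DMR"]
        clones = []
        for _ in range(200):
            label = labels[rng.choice(4, p=probs)]
            pat = sample_pattern("H19_DMR", label, 17, rng)
            calls = h19_calls(int((pat == 0).sum()))
            clones.append((calls, {"H19_DMR": classify_h19(calls)}))
        s = summarize_patient(clones, "P1", "OZ", h19, schemes=["H19_DMR"])
        for label, p in zip(labels, probs):
            se = math.sqrt(p * (1 - p) / 200)
            assert abs(s.category_percentages["H19_DMR"][label] / 100 - p) <= 3 * se


class TestLine1Aggregation:
    def test_single_fully_methylated_clone(self):
        assert aggregate_line1([(M,) * 19]) == (19, 19, 100.0)

    def test_variable_clone_cpg_counts_pool_denominator(self):
        clones = [(M,) * 10 + (U,) * 7 + (X,) * 2, (M,) * 19]
        n_total, n_meth, pct = aggregate_line1(clones)
        assert n_total == 36
        assert n_meth == 29
        assert pct == pytest.approx(100 * 29 / 36)

    def test_zero_called_cpgs_is_error(self):
        with pytest.raises(ValueError):
            aggregate_line1([(X, X, K)])
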