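import math
from pathlib import Path

import numpy as np
import pytest

from bsclones.amplicons import ConfigError, informative_cpgs
from bsclones.bisulfite import bisulfite_convert, conversion_stats, orient_and_align
from bsclones.classify import classify_dazl, classify_h19
from bsclones.simulate import (
    ErrorModel,
    GroupConfig,
    SimulationConfig,
    ZERO_ERROR,
    design_clone_counts,
    generate_clone,
    generate_cohorts,
    line1_pattern_from_design,
    sample_pattern,
    study_default_configs,
    truth_calls,
)


class TestSamplePattern:
    def test_complete_methylation_forced(self, rng):
        pat = sample_pattern("H19_DMR", "complete_methylation", 17, rng)
        assert pat.sum() == 17

    def test_severe_bin_count_range(self, rng):
        for _ in range(50):
            pat = sample_pattern("H19_DMR", "severe_hypomethylation", 17, rng)
            assert 9 <= (pat == 0).sum() <= 16

    @pytest.mark.parametrize("scheme,classifier,n", [
        ("H19_DMR", classify_h19, 17),
        ("DAZL", classify_dazl, 31),
    ])
    def test_round_trip_by_construction(self, scheme, classifier, n, rng):
        from bsclones.classify import SCHEME_LABELS
        from bsclones.bisulfite import Call

        for label in SCHEME_LABELS[scheme]:
            for _ in range(250):
                pat = sample_pattern(scheme, label, n, rng)
                calls = tuple(
                    Call.METHYLATED if b else Call.UNMETHYLATED for b in pat
                )
                assert classifier(calls).label == label

    def test_infeasible_category_raises(self, rng):
        # 2 CpGs: no count satisfies 0 < u/2 < 0.5
        with pytest.raises(ConfigError):
            sample_pattern("H19_DMR", "mild_hypomethylation", 2, rng)


class TestGenerateClone:
    def test_zero_error_equals_pure_conversion(self, h19, rng):
        pattern = np.ones(h19.n_cpgs, dtype=np.int8)
        rec = generate_clone(h19, pattern, ZERO_ERROR, rng)
        assert rec.sequence == bisulfite_convert(h19.sequence, set(h19.cpg_positions))
        assert rec.orientation == "+"

    def test_total_conversion_failure(self, h19, rng):
        em = ErrorModel(failed_conversion_rate=1.0, reverse_orientation_probability=0.0)
        rec = generate_clone(h19, np.ones(h19.n_cpgs, dtype=np.int8), em, rng)
        stats = conversion_stats(orient_and_align(rec.sequence, h19), h19)
        assert stats.conversion_rate == 0.0
        assert not stats.qc_pass

    def test_failed_conversion_rate_calibrated(self, h19, rng):
        # empirical retained-C fraction within 3 SE of the configured rate
        em = ErrorModel(
            failed_conversion_rate=0.02,
            over_conversion_rate=0.0,
            sequencing_substitution_rate=0.0,
            reverse_orientation_probability=0.0,
        )
        n_sites = len(h19.noncpg_c_positions())
        pattern = np.ones(h19.n_cpgs, dtype=np.int8)
        draws = 2000
        retained = sum(
            generate_clone(h19, pattern, em, rng).n_failed_conversions
            for _ in range(draws)
        )
        total = draws * n_sites
        se = math.sqrt(0.02 * 0.98 / total)
        assert abs(retained / total - 0.02) <= 3 * se

    def test_snp_t_allele_reads_as_t(self, h19, rng):
        pattern = np.ones(h19.n_cpgs, dtype=np.int8)
        rec = generate_clone(h19, pattern, ZERO_ERROR, rng, snp_allele="T")
        p = h19.cpg_positions[6]  # masked ordinal 7
        assert rec.sequence[p - 1] == "T"

    def test_pattern_length_checked(self, h19, rng):
        with pytest.raises(ConfigError):
            generate_clone(h19, [1, 0], ZERO_ERROR, rng)


class TestLine1CopyVariation:
    def test_disrupted_cpgs_become_missing(self, line1, rng):
        pattern = np.ones(line1.n_cpgs, dtype=np.int8)
        rec = generate_clone(
            line1, pattern, ZERO_ERROR, rng, disrupted_cpgs=(3, 11)
        )
        from bsclones.bisulfite import Call, call_states

        calls = call_states(orient_and_align(rec.sequence, line1), line1)
        assert calls[2] is Call.MISSING and calls[10] is Call.MISSING
        assert sum(c is Call.METHYLATED for c in calls) == 17

    def test_mean_called_cpgs_under_disruption(self, line1, rng):
        # disruption probability 0.1 on 19 CpGs: mean called ~ 17.1
        n = 3000
        called = 0
        for _ in range(n):
            disrupted = [o for o in range(1, 20) if rng.random() < 0.1]
            called += 19 - len(disrupted)
        mean = called / n
        se = math.sqrt(19 * 0.1 * 0.9 / n)
        assert abs(mean - 17.1) <= 3 * se

    def test_design_partition_exact(self):
        for n_clones, total, meth in [(105, 1785, 1425), (103, 1736, 1301), (110, 1968, 1596)]:
            design = design_clone_counts(n_clones, total, meth, 19)
            assert sum(c for c, _ in design) == total
            assert sum(m for _, m in design) == meth
            assert all(0 <= m <= c <= 19 for c, m in design)

    def test_pattern_from_design(self, line1, rng):
        pattern, disrupted = line1_pattern_from_design(line1, 17, 13, rng)
        assert len(disrupted) == 2
        assert pattern.sum() == 13
        assert all(pattern[o - 1] == 0 for o in disrupted)


class TestCohortGeneration:
    def test_same_seed_bit_identical(self, tmp_path):
        cfgs = study_default_configs(7, n_patients=2, clones_per_patient=3, line1_n_patients=2)
        a = tmp_path / "a"
        b = tmp_path / "b"
        generate_cohorts(cfgs, a)
        generate_cohorts(study_default_configs(7, n_patients=2, clones_per_patient=3, line1_n_patients=2), b)
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_extending_cohort_preserves_earlier_patients(self, tmp_path):
        small = study_default_configs(7, n_patients=2, clones_per_patient=3, line1_n_patients=2)
        big = study_default_configs(7, n_patients=4, clones_per_patient=3, line1_n_patients=2)
        generate_cohorts(small, tmp_path / "small")
        generate_cohorts(big, tmp_path / "big")
        f = "fasta/NZ02_H19.fa"
        assert (tmp_path / "small" / f).read_bytes() == (tmp_path / "big" / f).read_bytes()

    def test_study_design_sample_sheet_rows(self, tmp_path):
        # 3 groups x 20 patients -> 60 sample-sheet rows per amplicon
        cfgs = study_default_configs(1, clones_per_patient=2, line1_n_patients=20)
        sheet, truth = generate_cohorts(cfgs, tmp_path)
        lines = sheet.read_text().splitlines()
        rows = [l.split("\t") for l in lines[1:]]
        for amp in ("H19", "DAZL", "LINE1"):
            assert sum(1 for r in rows if r[2] == amp) == 60

    def test_truth_categories_match_patterns(self, tmp_path):
        cfgs = study_default_configs(
            3, n_patients=2, clones_per_patient=5, error_model=ZERO_ERROR, line1_n_patients=2
        )
        _, truth_path = generate_cohorts(cfgs, tmp_path)
        import pandas as pd

        truth = pd.read_csv(truth_path, sep="\t")
        h19 = truth[truth.amplicon == "H19"]
        assert set(h19.true_H19_DMR) <= {
            "complete_methylation",
            "mild_hypomethylation",
            "severe_hypomethylation",
            "complete_unmethylation",
        }
        assert (truth[truth.amplicon == "LINE1"].true_pattern.str.len() == 19).all()

    def test_misassignment_increases_with_over_conversion(self, h19, rng):
        # fully methylated clones: any over-converted informative CpG flips
        # the bin, so misassignment grows with the over-conversion rate
        from bsclones.bisulfite import call_states, orient_and_align
        from bsclones.classify import classify_h19

        pattern = np.ones(h19.n_cpgs, dtype=np.int8)
        fractions = []
        for r in (0.0, 0.05, 0.25):
            em = ErrorModel(0.0, r, 0.0, 0.0)
            wrong = 0
            for _ in range(40):
                rec = generate_clone(h19, pattern, em, rng)
                calls = call_states(orient_and_align(rec.sequence, h19), h19)
                wrong += classify_h19(calls).label != "complete_methylation"
            fractions.append(wrong / 40)
        assert fractions[0] == 0.0
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_qc_failure_rate_tracks_failed_conversion(self, h19, rng, tmp_path):
        # QC failures ~0 at rate 0 and increase with the failure rate
        from bsclones.pipeline import PipelineConfig, process_clone

        config = PipelineConfig()
        rates = [0.0, 0.02, 0.1]
        fail_fracs = []
        pattern = np.ones(h19.n_cpgs, dtype=np.int8)
        for r in rates:
            em = ErrorModel(r, 0.0, 0.0, 0.0)
            fails = 0
            for i in range(60):
                rec = generate_clone(h19, pattern, em, rng, clone_id=f"c{i}")
                _, calls = process_clone(rec.clone_id, rec.sequence, h19, config)
                fails += calls is None
            fail_fracs.append(fails / 60)
        assert fail_fracs[0] == 0.0
        assert fail_fracs[0] <= fail_fracs[1] <= fail_fracs[2]
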