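"""Peak-calling cascade: window scores, gates, merging, dependence,
summits, and the replicate-level high-confidence test."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6acall import (CoverageSet, GeneModel, PeakCallingParams, SampleMeta,
                     call_gene_peaks, call_sample_peaks, gene_expression_filter,
                     log_ratio_ttest, merge_peaks, remove_input_peaks,
                     score_windows)
from m6acall.peaks import M6A_DEPENDENT, M6A_INDEPENDENT, MergedPeak, \
    classify_dependence, find_summit, high_confidence_test, window_spans

from oracles import brute_force_window_scores, closed_form_ttest

PARAMS = PeakCallingParams()


def profile_300():
    """300-nt transcript, depth 10 everywhere except [100, 200) = 40."""
    d = np.full(300, 10.0)
    d[100:200] = 40.0
    return d


class TestScoreWindows:
    def test_enrichment_profile(self):
        scores = {(w.start, w.end): w for w in score_windows(profile_300(), "g")}
        assert scores[(100, 200)].enrichment == pytest.approx(4.0)
        assert scores[(100, 200)].mean_depth == pytest.approx(40.0)
        assert scores[(50, 150)].enrichment == pytest.approx(2.5)

    def test_uniform_depth_all_windows_unity(self):
        for w in score_windows(np.full(437, 17.0), "g"):
            assert w.enrichment == pytest.approx(1.0)

    def test_scaling_leaves_enrichment_changes_depth(self):
        base = score_windows(profile_300(), "g")
        scaled = score_windows(profile_300() * 7, "g")
        for a, b in zip(base, scaled):
            assert b.enrichment == pytest.approx(a.enrichment)
            assert b.mean_depth == pytest.approx(7 * a.mean_depth)

    def test_trailing_window_anchored_at_end(self):
        spans = window_spans(320, PARAMS)
        assert spans[-1] == (220, 320)
        assert spans[0] == (0, 100)
        # short transcript: single window covering everything
        assert window_spans(60, PARAMS) == [(0, 60)]

    def test_zero_length_transcript_raises(self):
        with pytest.raises(ValueError):
            window_spans(0, PARAMS)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            score_windows(np.zeros(200), "g")


class TestGates:
    def test_enrichment_exactly_three_rejected(self):
        d = np.full(200, 10.0)
        d[0:100] = 30.0  # window [0,100) enrichment exactly 3.0... median is 20
        # construct exactly: median 10, window mean 30 -> use longer flat tail
        d = np.full(1000, 10.0)
        d[0:100] = 30.0
        scores = score_windows(d, "g")
        w = next(s for s in scores if (s.start, s.end) == (0, 100))
        assert w.enrichment == pytest.approx(3.0)
        assert (0, 100) not in call_sample_peaks(d, "g")

    def test_depth_gate_independent_of_enrichment(self):
        d = np.full(1000, 2.0)
        d[0:100] = 9.0  # enrichment 4.5 but mean depth 9 < 10
        assert call_sample_peaks(d, "g") == []

    def test_passing_window_called(self):
        assert (100, 200) in call_sample_peaks(profile_300(), "g")


class TestRemoveInputPeaks:
    @pytest.mark.parametrize("ip, inp, expected", [
        ([(100, 200)], [(150, 250)], []),           # 50-base overlap removed
        ([(100, 200)], [], [(100, 200)]),
        ([(100, 200)], [(100, 200)], []),           # identical removed
        ([(100, 200)], [(200, 300)], [(100, 200)]),  # book-ended is not overlap
    ])
    def test_examples(self, ip, inp, expected):
        assert remove_input_peaks(ip, inp) == expected


class TestMergePeaks:
    @pytest.mark.parametrize("intervals, expected", [
        ([(100, 200), (150, 250)], [(100, 250)]),
        ([(100, 200), (200, 300)], [(100, 300)]),   # book-ended merge
        ([(100, 200), (300, 400)], [(100, 200), (300, 400)]),
        ([], []),
    ])
    def test_examples(self, intervals, expected):
        assert merge_peaks(intervals) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 120)), max_size=20))
    def test_output_sorted_disjoint_covering(self, raw):
        intervals = [(s, s + w) for s, w in raw]
        merged = merge_peaks(intervals)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2  # sorted, disjoint, not book-ended
        covered = set()
        for s, e in merged:
            covered.update(range(s, e))
        want = set()
        for s, e in intervals:
            want.update(range(s, e))
        assert covered == want


def build_coverage(gene, wt_ip, cat_ip, wt_in=None, cat_in=None):
    """CoverageSet with 3 replicates per genotype per fraction; per-genotype
    transcript profiles are given in transcript orientation."""
    cov = CoverageSet()
    L = gene.transcript_length
    base = np.full(L, 10.0)
    for rep in range(1, 4):
        for genotype, ip, inp in (("WT", wt_ip, wt_in), ("cat", cat_ip, cat_in)):
            for fraction, prof in (("IP", ip), ("input", inp if inp is not None else base)):
                depth = np.asarray(prof, dtype=float)
                arr = np.zeros(gene.transcript_end + 50)
                oriented = depth[::-1] if gene.strand == "-" else depth
                arr[gene.transcript_start:gene.transcript_end] = oriented
                cov.add(SampleMeta(genotype, fraction, rep), gene.chrom, gene.strand, arr)
    return cov


GENE = GeneModel("g", "chr1", "+", 60, 310, utr5_len=10, utr3_len=50)  # transcript [50, 360)


class TestExpressionFilter:
    def test_all_expressed(self):
        cov = build_coverage(GENE, np.full(310, 12.0), np.full(310, 12.0))
        assert gene_expression_filter(cov, GENE)

    def test_one_zero_median_sample_fails(self):
        cov = build_coverage(GENE, np.full(310, 12.0), np.full(310, 12.0))
        # overwrite one IP replicate with majority-zero coverage
        arr = np.zeros(GENE.transcript_end + 50)
        arr[50:180] = 30.0  # <50% of the 310-nt transcript covered
        cov.add(SampleMeta("cat", "IP", 2), "chr1", "+", arr)
        assert not gene_expression_filter(cov, GENE)


class TestDependence:
    def make_peak(self):
        return MergedPeak("g", 100, 200, 150, 250)

    def score_case(self, wt_level, cat_level):
        wt = np.full(310, 10.0)
        wt[100:200] = wt_level
        cat = np.full(310, 10.0)
        cat[100:200] = cat_level
        cov = build_coverage(GENE, wt, cat)
        return classify_dependence(self.make_peak(), cov, GENE)

    def test_ratio_above_threshold_dependent(self):
        assert self.score_case(40.0, 12.0).dependence == M6A_DEPENDENT

    def test_equal_scores_independent(self):
        peak = self.score_case(40.0, 40.0)
        assert peak.wt_score == pytest.approx(peak.cat_score)
        assert peak.dependence == M6A_INDEPENDENT

    def test_ratio_exactly_175_inclusive(self):
        peak = self.make_peak()
        peak.wt_score, peak.cat_score = 3.5, 2.0
        wt = np.full(310, 10.0); wt[100:200] = 35.0
        cat = np.full(310, 10.0); cat[100:200] = 20.0
        peak = classify_dependence(self.make_peak(),
                                   build_coverage(GENE, wt, cat), GENE)
        assert peak.wt_score / peak.cat_score == pytest.approx(1.75)
        assert peak.dependence == M6A_DEPENDENT

    def test_zero_cat_score_flagged_dependent(self):
        wt = np.full(310, 10.0); wt[100:200] = 40.0
        cat = np.full(310, 10.0)
        cov = build_coverage(GENE, wt, cat)
        # zero out cat IP coverage entirely inside the peak via median-0 guard:
        for rep in range(1, 4):
            arr = np.zeros(GENE.transcript_end + 50)
            cov.add(SampleMeta("cat", "IP", rep), "chr1", "+", arr)
        peak = classify_dependence(MergedPeak("g", 100, 200, 150, 250), cov, GENE)
        assert peak.dependence == M6A_DEPENDENT
        assert peak.cat_zero_flag


class TestSummit:
    def test_leftmost_tie(self):
        prof = np.full(310, 1.0)
        prof[100:104] = [5, 9, 9, 3]
        cov = build_coverage(GENE, prof, prof)
        peak = MergedPeak("g", 100, 104, 0, 0)
        assert find_summit(peak, cov, GENE) == 101

    def test_single_base_peak(self):
        prof = np.full(310, 1.0)
        cov = build_coverage(GENE, prof, prof)
        assert find_summit(MergedPeak("g", 42, 43, 0, 0), cov, GENE) == 42

    def test_monotone_increasing_last_base(self):
        prof = np.arange(310, dtype=float) + 1
        cov = build_coverage(GENE, prof, prof)
        assert find_summit(MergedPeak("g", 10, 60, 0, 0), cov, GENE) == 59


class TestHighConfidence:
    def test_log2fc_of_known_ratios(self):
        log2fc, p = log_ratio_ttest([4.0, 4.4, 3.6], [1.0, 1.1, 0.9])
        assert log2fc == pytest.approx(2.0, abs=0.01)
        _, p_oracle = closed_form_ttest(np.log2([4.0, 4.4, 3.6]).tolist(),
                                        np.log2([1.0, 1.1, 0.9]).tolist())
        assert p == pytest.approx(p_oracle)
        assert p < 0.01

    def test_identical_ratios_zero_fc(self):
        log2fc, _ = log_ratio_ttest([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert log2fc == 0.0

    def test_high_variance_not_significant(self):
        log2fc, p = log_ratio_ttest([2.0, 60.0, 0.4], [1.0, 1.05, 0.95])
        assert log2fc > 0.8
        assert p > 0.01  # fold change large but variance kills the call

    def test_fewer_than_two_replicates_raises(self):
        with pytest.raises(ValueError):
            log_ratio_ttest([2.0], [1.0, 1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_closed_form_oracle(self, seed):
        r = np.random.default_rng(seed)
        wt = r.uniform(0.5, 8.0, 3).tolist()
        cat = r.uniform(0.5, 8.0, 3).tolist()
        log2fc, p = log_ratio_ttest(wt, cat)
        t_o, p_o = closed_form_ttest(np.log2(wt).tolist(), np.log2(cat).tolist())
        assert p == pytest.approx(p_o, rel=1e-9)
        assert log2fc == pytest.approx(np.mean(np.log2(wt)) - np.mean(np.log2(cat)))


class TestCascade:
    def test_uniform_coverage_no_peaks(self):
        cov = build_coverage(GENE, np.full(310, 20.0), np.full(310, 20.0))
        assert call_gene_peaks(cov, GENE) == []

    def test_peak_present_in_input_removed(self):
        prof = np.full(310, 10.0)
        prof[100:200] = 60.0
        cov = build_coverage(GENE, prof, prof, wt_in=prof, cat_in=prof)
        assert call_gene_peaks(cov, GENE) == []

    def test_wt_specific_peak_called_dependent(self):
        wt = np.full(310, 10.0)
        wt[100:200] = 60.0
        cat = np.full(310, 10.0)
        peaks = call_gene_peaks(build_coverage(GENE, wt, cat), GENE)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.dependence == M6A_DEPENDENT
        assert p.start <= 100 and p.end >= 200
        assert p.start <= p.summit < p.end
        assert 100 <= p.summit < 200
        assert p.high_confidence
        # genomic coordinates map back into the transcript
        assert GENE.transcript_start <= p.genomic_start < p.genomic_end <= GENE.transcript_end

    def test_minus_strand_genomic_mapping(self):
        gene = GeneModel("m", "chr1", "-", 60, 310, utr5_len=50, utr3_len=10)
        wt = np.full(310, 10.0)
        wt[100:200] = 60.0  # transcript orientation
        cat = np.full(310, 10.0)
        peaks = call_gene_peaks(build_coverage(gene, wt, cat), gene)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.summit_genomic == gene.transcript_to_genomic(p.summit)
        assert gene.genomic_to_transcript(p.summit_genomic) == p.summit


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_window_scanner_matches_brute_force(seed):
    """Vectorized-ish scanner equals an explicit loop recomputing everything."""
    r = np.random.default_rng(seed)
    L = int(r.integers(40, 700))
    tdepth = r.integers(1, 80, L).astype(float)
    got = score_windows(tdepth, "g")
    want = brute_force_window_scores(tdepth.tolist())
    assert [(w.start, w.end) for w in got] == [(s, e) for s, e, _, _ in want]
    for w, (_, _, mean, enr) in zip(got, want):
        assert w.mean_depth == pytest.approx(mean)
        assert w.enrichment == pytest.approx(enr)
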