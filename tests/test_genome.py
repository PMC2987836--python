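"""Non-coding extraction, negative sampling, and genome scanning."""

import numpy as np
import pytest

from sitesleuth.genome import (
    GenomeAnnotation,
    PwmWindowScorer,
    SvmWindowScorer,
    eligible_window_starts,
    extract_noncoding,
    sample_negative_windows,
    scan,
)
from sitesleuth.mapping import (
    SiteSequence,
    map_sequence_to_features,
    reverse_complement,
)
from sitesleuth.pwm import AdditiveScorer, bvh_train
from sitesleuth.svm import LinearClassifier, PenaltyPair, TrainingSet, decision_value, train_svm
from sitesleuth.simulate import generate_genome


def constant_scorer(L, accept):
    """A PWM-style scorer that scores every window 0; cutoff selects all or none."""
    s = AdditiveScorer()
    s.matrix = np.zeros((4, L))
    s.offset = 0.0
    s.cutoff = -1.0 if accept else 1.0
    return PwmWindowScorer(model=s)


def noncoding_mask_oracle(length, coding):
    mask = np.ones(length, dtype=bool)
    for s, e in coding:
        mask[s:e] = False
    return mask


class TestExtractNoncoding:
    def test_hand_example(self):
        ann = GenomeAnnotation(sequences={"c": "A" * 30},
                               coding={"c": [(5, 10), (8, 15), (20, 25)]})
        regions = extract_noncoding(ann)
        assert regions.regions == [("c", 0, 5), ("c", 15, 20), ("c", 25, 30)]
        assert regions.total_length == 15

    def test_matches_boolean_mask_oracle(self, rng):
        length = 500
        coding = sorted((int(s), int(s) + int(w)) for s, w in
                        zip(rng.integers(0, 480, 15), rng.integers(1, 30, 15)))
        coding = [(s, min(e, length)) for s, e in coding]
        ann = GenomeAnnotation(sequences={"c": "A" * length}, coding={"c": coding})
        mask = noncoding_mask_oracle(length, coding)
        got = np.zeros(length, dtype=bool)
        for _, s, e in extract_noncoding(ann).regions:
            assert not got[s:e].any()  # disjoint
            got[s:e] = True
        assert (got == mask).all()

    def test_fully_coding_sequence_warns(self, caplog):
        ann = GenomeAnnotation(sequences={"c": "ACGT"}, coding={"c": [(0, 4)]})
        with caplog.at_level("WARNING"):
            regions = extract_noncoding(ann)
        assert regions.regions == []
        assert "entirely coding" in caplog.text

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomeAnnotation(sequences={"c": "ACGT"}, coding={"c": [(2, 9)]})


class TestEligibleWindows:
    def test_interior_region_of_length_l_plus_two_has_three_starts(self):
        # region [10, 16) in a length-30 sequence, L = 4: starts 10, 11, 12
        ann = GenomeAnnotation(sequences={"c": "A" * 30}, coding={"c": [(0, 10), (16, 30)]})
        starts = eligible_window_starts(ann, extract_noncoding(ann), L=4)
        assert starts == [("c", 10), ("c", 11), ("c", 12)]

    def test_linear_termini_lack_context(self):
        ann = GenomeAnnotation(sequences={"c": "A" * 10}, coding={"c": []})
        starts = eligible_window_starts(ann, extract_noncoding(ann), L=4)
        # start 0 has no left context; start 6 has no right context
        assert starts == [("c", s) for s in (1, 2, 3, 4, 5)]

    def test_circular_sequence_wraps(self):
        ann = GenomeAnnotation(sequences={"c": "A" * 10}, coding={"c": []},
                               circular={"c": True})
        starts = eligible_window_starts(ann, extract_noncoding(ann), L=4)
        assert starts == [("c", s) for s in range(7)]


class TestNegativeSampling:
    @pytest.fixture()
    def annotation(self):
        genome = generate_genome(400, seed=4)
        return GenomeAnnotation(sequences={"c": genome}, coding={"c": [(100, 250)]})

    def test_deterministic_and_within_bounds(self, annotation):
        regions = extract_noncoding(annotation)
        a = sample_negative_windows(annotation, regions, L=6, count=30, seed=9)
        b = sample_negative_windows(annotation, regions, L=6, count=30, seed=9)
        assert [s.origin.start for s in a] == [s.origin.start for s in b]
        assert len(a) == 30
        g = annotation.sequences["c"]
        for site in a:
            o = site.origin
            assert site.core == g[o.start:o.end]
            assert site.left_context == g[o.start - 1]
            assert site.right_context == g[o.end]
            assert not (o.start < 250 and o.end > 100)  # non-coding only

    def test_exclusion_intervals_respected(self, annotation):
        regions = extract_noncoding(annotation)
        sites = sample_negative_windows(annotation, regions, L=6, count=1000,
                                        seed=0, exclude=[("c", 10, 40)])
        for site in sites:
            o = site.origin
            assert not (o.start < 40 and o.end > 10)

    def test_short_supply_returns_all_with_warning(self, annotation, caplog):
        regions = extract_noncoding(annotation)
        with caplog.at_level("WARNING"):
            sites = sample_negative_windows(annotation, regions, L=6,
                                            count=10_000, seed=0)
        n_eligible = len(eligible_window_starts(annotation, regions, L=6))
        assert len(sites) == n_eligible
        assert "eligible windows" in caplog.text

    def test_no_eligible_windows_is_an_error(self):
        ann = GenomeAnnotation(sequences={"c": "ACGTAC"}, coding={"c": [(0, 5)]})
        with pytest.raises(ValueError):
            sample_negative_windows(ann, extract_noncoding(ann), L=4)


class TestScan:
    @pytest.fixture()
    def annotation(self):
        genome = generate_genome(200, seed=2)
        return GenomeAnnotation(sequences={"c": genome}, coding={"c": [(60, 140)]})

    def test_accept_all_reports_every_window_on_both_strands(self, annotation):
        preds = scan(constant_scorer(5, accept=True), annotation,
                     extract_noncoding(annotation))
        # regions [0,60) and [140,200): 56 + 56 windows, twice for strands
        assert preds.n_predictions == 2 * (56 + 56)
        assert set(preds.records["strand"]) == {"+", "-"}
        assert preds.skipped_windows == 0  # no context needed

    def test_reject_all_is_empty(self, annotation):
        preds = scan(constant_scorer(5, accept=False), annotation,
                     extract_noncoding(annotation))
        assert preds.n_predictions == 0
        assert list(preds.records.columns) == ["seq_id", "start", "end",
                                               "strand", "score", "sequence"]

    def test_no_hit_overlaps_coding(self, annotation):
        preds = scan(constant_scorer(7, accept=True), annotation,
                     extract_noncoding(annotation))
        for _, row in preds.records.iterrows():
            assert not (row.start < 140 and row.end > 60)

    def test_minus_strand_rows_carry_forward_coordinates_and_rc_sequence(self, annotation):
        g = annotation.sequences["c"]
        preds = scan(constant_scorer(5, accept=True), annotation,
                     extract_noncoding(annotation))
        minus = preds.records[preds.records.strand == "-"]
        assert len(minus) > 0
        for _, row in minus.iterrows():
            assert row.sequence == reverse_complement(g[row.start:row.end])

    def test_pwm_hits_match_direct_window_classification(self, annotation):
        model = bvh_train(["TGACGT", "TGACGA", "TGACTT", "TAACGT"])
        regions = extract_noncoding(annotation)
        preds = scan(PwmWindowScorer(model=model), annotation, regions)
        g = annotation.sequences["c"]
        expected = set()
        for _, s, e in regions.regions:
            for start in range(s, e - 6 + 1):
                w = g[start:start + 6]
                if model.classify(w):
                    expected.add((start, "+"))
                if model.classify(reverse_complement(w)):
                    expected.add((start, "-"))
        got = {(row.start, row.strand) for _, row in preds.records.iterrows()}
        assert got == expected

    def test_palindromic_hit_is_reported_on_both_strands(self):
        # plant a palindrome; an exact-match scorer fires on + and - alike
        core = "TGATCA"  # reverse complement of itself
        genome = "AAAAAAAA" + core + "AAAAAAAA"
        ann = GenomeAnnotation(sequences={"c": genome}, coding={"c": []})
        model = bvh_train([core] * 3)
        model.cutoff = -0.1  # exact matches score 0
        preds = scan(PwmWindowScorer(model=model), ann, extract_noncoding(ann))
        strands = sorted(preds.records[preds.records.start == 8]["strand"])
        assert strands == ["+", "-"]

    def test_svm_scan_equals_explicit_feature_mapping(self, annotation, bundle):
        L = 6
        rng = np.random.default_rng(3)
        regions = extract_noncoding(annotation)
        pos = sample_negative_windows(annotation, regions, L, count=12, seed=1)
        neg = sample_negative_windows(annotation, regions, L, count=40, seed=2)
        X = np.vstack([[map_sequence_to_features(s, bundle).values for s in pos],
                       [map_sequence_to_features(s, bundle).values for s in neg]])
        y = np.concatenate([np.ones(12), -np.ones(40)])
        clf = train_svm(TrainingSet(X, y), PenaltyPair(10.0, 1.0))
        scorer = SvmWindowScorer(clf=clf, tables=bundle, L=L)
        preds = scan(scorer, annotation, regions)
        g = annotation.sequences["c"]
        # every reported score equals the slow path's decision value
        assert preds.n_predictions > 0
        for _, row in preds.records.iterrows():
            if row.strand == "+":
                site = SiteSequence(core=g[row.start:row.end],
                                    left_context=g[row.start - 1],
                                    right_context=g[row.end])
            else:
                site = SiteSequence(core=reverse_complement(g[row.start:row.end]),
                                    left_context=reverse_complement(g[row.end]),
                                    right_context=reverse_complement(g[row.start - 1]))
            slow = decision_value(clf, map_sequence_to_features(site, bundle).values)
            assert row.score == pytest.approx(slow, abs=1e-8)
            assert slow > 0

    def test_svm_scan_skips_context_free_terminus_windows(self, bundle):
        genome = generate_genome(40, seed=5)
        ann = GenomeAnnotation(sequences={"c": genome}, coding={"c": []})
        clf = LinearClassifier(w=np.zeros(28 * 6 - 6), d=1.0)  # accepts everything
        scorer = SvmWindowScorer(clf=clf, tables=bundle, L=6)
        preds = scan(scorer, ann, extract_noncoding(ann))
        # windows at starts 0 and 34 lack context: 2 skipped, 33 scored per strand
        assert preds.skipped_windows == 2
        assert preds.n_predictions == 2 * 33

    def test_circular_sequence_has_no_skipped_windows(self, bundle):
        genome = generate_genome(40, seed=5)
        ann = GenomeAnnotation(sequences={"c": genome}, coding={"c": []},
                               circular={"c": True})
        clf = LinearClassifier(w=np.zeros(28 * 6 - 6), d=1.0)
        preds = scan(SvmWindowScorer(clf=clf, tables=bundle, L=6), ann,
                     extract_noncoding(ann))
        assert preds.skipped_windows == 0
        assert preds.n_predictions == 2 * 35

    def test_tsv_and_bed_output(self, annotation, tmp_path):
        preds = scan(constant_scorer(5, accept=True), annotation,
                     extract_noncoding(annotation), model_id="m")
        preds.to_tsv(tmp_path / "p.tsv")
        preds.to_bed(tmp_path / "p.bed")
        tsv = (tmp_path / "p.tsv").read_text().splitlines()
        assert tsv[0].split("\t") == ["seq_id", "start", "end", "strand",
                                      "score", "sequence"]
        bed = (tmp_path / "p.bed").read_text().splitlines()
        assert len(bed) == preds.n_predictions
        assert bed[0].split("\t")[0] == "c"
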