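"""PWM baselines: hand-computed scores, closed forms, QPMEME optimality."""

import math

import numpy as np
import pytest

from sitesleuth.pwm import (
    Background,
    BvhModel,
    MatchModel,
    background_frequencies,
    build_count_matrix,
    bvh_train,
    load_model,
    match_train,
    matrix_search_train,
    qpmeme_background_variance,
    qpmeme_train,
    save_model,
)

from oracles import qpmeme_oracle


def random_sites(rng, n, L):
    return ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]


class TestCountMatrix:
    def test_counts_by_hand(self):
        cm = build_count_matrix(["AC", "AG", "TG"])
        # position 0: A=2, T=1; position 1: C=1, G=2
        assert cm.counts.tolist() == [[2, 0], [0, 1], [0, 2], [1, 0]]
        assert cm.N == 3 and cm.L == 2
        assert np.allclose(cm.frequencies.sum(axis=0), 1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_count_matrix(["AC", "ACG"])

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="N"):
            build_count_matrix(["AN"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_count_matrix([])


class TestBackground:
    def test_frequencies_by_hand(self):
        bg = background_frequencies(["AACG", "TT"])
        assert np.allclose(bg.p, [2 / 6, 1 / 6, 1 / 6, 2 / 6])

    def test_missing_base_requires_smoothing(self):
        with pytest.raises(ValueError):
            background_frequencies(["AAAA"])
        bg = background_frequencies(["AAAA"], smoothing=1.0)
        assert np.allclose(bg.p, [5 / 8, 1 / 8, 1 / 8, 1 / 8])

    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Background(p=np.array([0.5, 0.5, 0.5, 0.5]))


class TestBvh:
    def test_hand_score(self):
        # sites {AA, AC}: S = AT scores 0 + ln(0.5/1.5)
        model = bvh_train(["AA", "AC"])
        assert model.score("AT") == pytest.approx(math.log(1 / 3))
        # modal base scores zero at every position
        assert model.score("AA") == pytest.approx(math.log(1.5 / 1.5))

    def test_identical_sites_score_zero_and_classify_negative(self):
        # all scores equal the cutoff; strict '>' classifies the site negative
        model = bvh_train(["ACGT"] * 5)
        assert model.score("ACGT") == 0.0
        assert model.cutoff == 0.0
        assert not model.classify("ACGT")

    def test_scores_never_positive(self, rng):
        sites = random_sites(rng, 20, 6)
        model = bvh_train(sites)
        assert (model.score_many(sites) <= 1e-12).all()

    def test_modal_tie_is_deterministic(self):
        # A and C tie at position 0; argmax picks A
        model = BvhModel(count_matrix=build_count_matrix(["A", "C"]))
        assert model.score("A") == pytest.approx(0.0)
        assert model.score("C") == pytest.approx(0.0)
        assert model.score("G") == pytest.approx(math.log(0.5 / 1.5))


class TestMatch:
    def test_endpoints_are_zero_and_one(self):
        sites = ["AAAA", "AAAC", "AAAG"]
        model = match_train(sites)
        # best-matching sequence per position -> 1; worst -> 0
        assert model.score("AAAA") == pytest.approx(1.0)
        assert model.score("TTTT") == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        sites = ["AAAA", "AAAC", "AAAG"]
        model = match_train(sites)
        I4 = math.log(4 / 3)  # 3 * (1/3) ln(4/3)
        assert model.information[:3] == pytest.approx([math.log(4)] * 3)
        assert model.information[3] == pytest.approx(I4)
        span = 3 * math.log(4) + I4 / 3
        assert model.score("AAAC") == pytest.approx(
            (3 * math.log(4) + I4 / 3) / span)
        assert model.score("AAAT") == pytest.approx(3 * math.log(4) / span)

    def test_all_scores_in_unit_interval(self, rng):
        model = match_train(random_sites(rng, 15, 8))
        probes = random_sites(rng, 50, 8)
        s = model.score_many(probes)
        assert ((0 - 1e-12 <= s) & (s <= 1 + 1e-12)).all()

    def test_uninformative_matrix_rejected(self):
        # perfectly uniform columns carry no information
        with pytest.raises(ValueError, match="uninformative"):
            match_train(["A", "C", "G", "T"])


class TestMatrixSearch:
    def test_identical_sites_closed_form(self):
        model = matrix_search_train(["ACGT"] * 4, Background.uniform())
        assert model.score("ACGT") == pytest.approx(4 * math.log(1.01 / 0.25))
        # every position mismatched: frequency 0 plus pseudocount
        assert model.score("CAAA") == pytest.approx(4 * math.log(0.01 / 0.25))

    def test_score_decreases_with_each_mismatch(self):
        model = matrix_search_train(["AAAA"] * 4, Background.uniform())
        seqs = ["AAAA", "AAAC", "AACC", "ACCC", "CCCC"]
        scores = [model.score(s) for s in seqs]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_background_shifts_scores(self):
        skew = Background(p=np.array([0.7, 0.1, 0.1, 0.1]))
        m_uniform = matrix_search_train(["AAAA"] * 3, Background.uniform())
        m_skew = matrix_search_train(["AAAA"] * 3, skew)
        # an A-rich background makes the A-consensus less surprising
        assert m_skew.score("AAAA") < m_uniform.score("AAAA")


class TestQpmeme:
    def test_single_site_closed_form(self):
        # one site, uniform background: eps_{S_j,j} = -1/L, others +1/(3L);
        # optimal variance 1/(3L) and the site constraint is active
        for L, site in ((4, "ACGT"), (6, "AACGTT")):
            model = qpmeme_train([site])
            assert model.score(site) == pytest.approx(-1.0, abs=1e-9)
            var = qpmeme_background_variance(model.epsilon, model.background)
            assert var == pytest.approx(1 / (3 * L), abs=1e-9)
            idx = ["ACGT".index(b) for b in site]
            assert model.epsilon[idx, np.arange(L)] == pytest.approx(-1 / L)

    def test_all_training_constraints_satisfied(self, rng):
        sites = random_sites(rng, 12, 5)
        model = qpmeme_train(sites)
        assert (model.score_many(sites) <= -1 + 1e-8).all()

    def test_matches_constrained_optimizer_oracle(self, rng):
        for seed in (0, 1):
            r = np.random.default_rng(seed)
            sites = random_sites(r, 6, 4)
            model = qpmeme_train(sites)
            ours = qpmeme_background_variance(model.epsilon, model.background)
            ref = qpmeme_oracle(sites, model.background.p)
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-10)

    def test_background_mean_energy_is_zero_per_column(self, rng):
        model = qpmeme_train(random_sites(rng, 8, 5))
        assert np.allclose(model.background.p @ model.epsilon, 0.0, atol=1e-10)

    def test_duplicating_sites_leaves_solution_unchanged(self, rng):
        sites = random_sites(rng, 5, 4)
        m1 = qpmeme_train(sites)
        m2 = qpmeme_train(sites + sites)
        assert np.allclose(m1.epsilon, m2.epsilon, atol=1e-7)

    def test_classification_convention_low_energy_is_site(self):
        model = qpmeme_train(["ACGT", "ACGA"])
        assert model.classify("ACGT")
        assert not model.classify("TTTT")


class TestCommon:
    def test_training_order_invariance(self, rng):
        sites = random_sites(rng, 10, 6)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        for train in (bvh_train, match_train,
                      lambda s: matrix_search_train(s, Background.uniform()),
                      qpmeme_train):
            a, b = train(sites), train(shuffled)
            probes = random_sites(rng, 10, 6)
            assert np.allclose(a.score_many(probes), b.score_many(probes),
                               atol=1e-8)

    @pytest.mark.parametrize("maker", [
        lambda s: bvh_train(s),
        lambda s: match_train(s),
        lambda s: matrix_search_train(s, Background.uniform()),
        lambda s: qpmeme_train(s),
    ])
    def test_serialization_round_trip(self, maker, rng, tmp_path):
        sites = random_sites(rng, 8, 5)
        model = maker(sites)
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        probes = random_sites(rng, 10, 5)
        assert np.allclose(model.score_many(probes), loaded.score_many(probes))
        assert loaded.cutoff == pytest.approx(model.cutoff)
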