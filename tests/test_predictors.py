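"""The three homology predictors and their scoring primitives."""

import math

import pytest

from hominf.predictors import (
    PredictorParams,
    combined_leaf_score,
    compile_background,
    predict_student_a,
    predict_student_b,
    predict_student_c,
    raw_template_score,
    template_quality_score,
    term_support,
)

from conftest import make_db, make_hits


class TestRawTemplateScore:
    def test_two_hit_hand_arithmetic(self):
        hits = make_hits("q", ("s1", 1e-2), ("s2", 1e-4))
        logs = [math.log(1e-2), math.log(1e-4)]
        mean = sum(logs) / 2
        sd = math.sqrt(sum((x - mean) ** 2 for x in logs))  # n-1 = 1
        assert raw_template_score(hits) == pytest.approx(mean + 2 * sd)
        assert raw_template_score(hits) == pytest.approx(-0.395, abs=5e-3)

    def test_single_hit_sd_zero(self):
        assert raw_template_score(make_hits("q", ("s1", 1e-3))) == pytest.approx(
            math.log(1e-3)
        )

    def test_identical_evalues(self):
        hits = make_hits("q", ("s1", 1e-5), ("s2", 1e-5), ("s3", 1e-5))
        assert raw_template_score(hits) == pytest.approx(math.log(1e-5))

    def test_no_hits_is_error(self):
        with pytest.raises(ValueError):
            raw_template_score(make_hits("q"))


class TestTemplateQualityScore:
    def test_extremes(self):
        background = [-10.0, -5.0, -1.0]
        assert template_quality_score(-100.0, background) == 1.0
        assert template_quality_score(0.0, background) == 0.0

    def test_ninety_percent_obtained_maps_to_point_one(self):
        background = [float(-i) for i in range(1, 11)]  # -1 .. -10
        # raw of -2 is reached (score <= raw) by the 9 values -2..-10
        assert template_quality_score(-2.0, background) == pytest.approx(0.1)

    def test_empty_background(self):
        with pytest.raises(ValueError):
            template_quality_score(0.0, [])


class TestTermSupport:
    def test_worked_two_hit_case(self, chain):
        db = make_db(("s1", ["a"]), ("s2", ["b"]))
        hits = make_hits("q", ("s1", 1e-4), ("s2", 1e-2))
        assert term_support("a", hits, db, chain) == pytest.approx(1.0)
        expected_b = math.log(1e-2) / (math.log(1e-4) + math.log(1e-2))
        assert term_support("b", hits, db, chain) == pytest.approx(expected_b)
        assert expected_b == pytest.approx(1 / 3)

    def test_absent_term_scores_zero(self, chain):
        db = make_db(("s1", ["a"]))
        hits = make_hits("q", ("s1", 1e-4))
        assert term_support("b", hits, db, chain) == 0.0

    def test_equal_evalues_collapse_to_hit_fraction(self, chain):
        db = make_db(("s1", ["b"]), ("s2", ["a"]), ("s3", ["a"]))
        hits = make_hits("q", ("s1", 1e-3), ("s2", 1e-3), ("s3", 1e-3))
        assert term_support("b", hits, db, chain) == pytest.approx(1 / 3)


class TestCombinedLeafScore:
    def test_chain_average_excludes_root(self, chain):
        supports = {"b": 1 / 3, "a": 1.0, "r": 1.0}
        assert combined_leaf_score("b", supports, chain) == pytest.approx(2 / 3)

    def test_all_ones(self, forked):
        supports = {t: 1.0 for t in forked.terms}
        assert combined_leaf_score("c", supports, forked) == 1.0

    def test_leaf_directly_under_root(self, chain):
        assert combined_leaf_score("a", {"a": 0.4}, chain) == pytest.approx(0.4)


class TestStudentA:
    def test_term_in_all_hits_scores_one(self, chain):
        db = make_db(*((f"s{i}", ["b"]) for i in range(6)))
        hits = make_hits("q", *((f"s{i}", 1e-10) for i in range(6)))
        pred = predict_student_a(hits, db, chain)
        assert pred.scores == {"b": 1.0, "a": 1.0}  # root stripped

    def test_term_in_five_of_six_scores_half(self, forked):
        db = make_db(*((f"s{i}", ["c"]) for i in range(5)), ("s5", ["f"]))
        hits = make_hits("q", *((f"s{i}", 1e-10) for i in range(6)))
        pred = predict_student_a(hits, db, forked)
        assert pred.scores.get("c") == 0.5
        strict = predict_student_a(
            hits, db, forked,
            PredictorParams(method="A", max_hits=6, max_evalue=0.1,
                            exclude_half_scores=True),
        )
        assert "c" not in strict.scores and "f" not in strict.scores

    def test_nested_leaves_cluster_keeps_deeper(self, chain):
        # a and b predicted as separate terms; branches {a,r} and {b,a,r}
        # overlap 2/2.5 = 0.8 >= 0.1 -> one cluster -> deeper leaf b kept;
        # the pair does not exceed 0.9 so no correction term appears.
        db = make_db(("s1", ["b"]), ("s2", ["a"]))
        hits = make_hits("q", ("s1", 1e-10), ("s2", 1e-10))
        pred = predict_student_a(hits, db, chain)
        assert set(pred.scores) == {"b", "a"}
        assert pred.scores["b"] == 0.5  # b was in 1 of 2 hits

    def test_high_overlap_correction_adds_common_term(self):
        # two sibling leaves under a deep shared chain: overlap 4/5 = 0.8;
        # lengthen the shared part to push overlap over 0.9
        from hominf.ontology import load_ontology

        edges = [("a", "r", "is_a")] + [
            (f"n{i}", f"n{i-1}" if i > 1 else "a", "is_a") for i in range(1, 10)
        ] + [("x", "n9", "is_a"), ("y", "n9", "is_a")]
        graph = load_ontology(edges)
        db = make_db(("s1", ["x"]), ("s2", ["y"]))
        hits = make_hits("q", ("s1", 1e-10), ("s2", 1e-10))
        pred = predict_student_a(hits, db, graph)
        # branches of x and y overlap 11/12 > 0.9 -> n9 re-injected
        assert pred.scores.get("n9") == 0.5

    def test_empty_hits_empty_prediction(self, chain):
        db = make_db(("s1", ["b"]))
        assert not predict_student_a(make_hits("q"), db, chain)

    def test_scores_restricted_to_half_and_one(self, forked):
        db = make_db(("s1", ["c"]), ("s2", ["f"]), ("s3", ["c", "f"]))
        hits = make_hits("q", ("s1", 1e-5), ("s2", 1e-4), ("s3", 1e-3))
        pred = predict_student_a(hits, db, forked)
        assert set(pred.scores.values()) <= {0.5, 1.0}


class TestStudentB:
    def test_single_hit_scores_tqs(self, chain):
        db = make_db(("s1", ["b"]))
        hits = make_hits("q", ("s1", 1e-3))
        pred = predict_student_b(hits, db, chain, background=[-100.0, -50.0])
        # raw = ln(1e-3) above the whole background -> TQS 0; CLS 1.0
        assert pred.scores == {"b": 0.0, "a": 0.0}
        pred2 = predict_student_b(hits, db, chain, background=[-1.0, -0.5])
        assert pred2.scores == {"b": 1.0, "a": 1.0}

    def test_worked_two_hit_case(self, chain):
        db = make_db(("s1", ["a"]), ("s2", ["b"]))
        hits = make_hits("q", ("s1", 1e-4), ("s2", 1e-2))
        params = PredictorParams(method="B", max_hits=250, max_evalue=0.1)
        # raw = mean(lnE) + 2 sd(lnE) ~= -0.395, below the whole background
        pred = predict_student_b(hits, db, chain, params, background=[1.0])
        # single leaf b: support(b)=1/3, support(a)=1.0 -> CLS = 2/3; TQS=1
        assert pred.scores["b"] == pytest.approx(2 / 3)
        assert pred.scores["a"] == pytest.approx(2 / 3)  # max-propagated leaf score

    def test_no_background_defaults_to_pure_leaf_score(self, chain):
        db = make_db(("s1", ["b"]))
        pred = predict_student_b(make_hits("q", ("s1", 1e-3)), db, chain)
        assert pred.scores["b"] == pytest.approx(1.0)

    def test_compile_background_sorted(self, chain):
        db = make_db(("s1", ["b"]), ("s2", ["a"]))
        tables = {
            "t1": make_hits("t1", ("s1", 1e-3)),
            "t2": make_hits("t2", ("s2", 1e-8)),
        }
        bg = compile_background(tables, db, PredictorParams.default("B"))
        assert bg == sorted(bg) and len(bg) == 2


class TestStudentC:
    def test_two_hits_hand_trace(self, chain):
        db = make_db(("s1", ["b"]), ("s2", ["b"]))
        hits = make_hits("q", ("s1", 1e-10, 80.0), ("s2", 1e-10, 90.0))
        pred = predict_student_c(hits, db, chain)
        # counts {b:2} -> cumulative {b:1, a:1, r:1}; identity max = 0.9
        assert pred.scores["b"] == pytest.approx(0.9)
        assert pred.scores["a"] == pytest.approx(0.9)

    def test_majority_leaf_wins(self, forked):
        db = make_db(*((f"s{i}", ["c"]) for i in range(3)), ("s3", ["f"]))
        hits = make_hits("q", *((f"s{i}", 1e-10, 90.0) for i in range(4)))
        pred = predict_student_c(hits, db, forked)
        assert "c" in pred.scores and "f" not in pred.scores

    def test_all_branches_keeps_both(self, forked):
        db = make_db(("s0", ["c"]), ("s1", ["f"]))
        hits = make_hits("q", ("s0", 1e-10, 90.0), ("s1", 1e-10, 90.0))
        pred = predict_student_c(
            hits, db, forked, PredictorParams(method="C", max_evalue=0.1,
                                              all_branches=True)
        )
        assert "c" in pred.scores and "f" in pred.scores

    def test_identity_kind_switches_factor_only(self, chain):
        db = make_db(("s1", ["b"]))
        hits = make_hits("q", ("s1", 1e-10, 90.0, 60.0))
        by_pos = predict_student_c(hits, db, chain)
        by_id = predict_student_c(
            hits, db, chain,
            PredictorParams(method="C", max_evalue=0.1, identity_kind="identity"),
        )
        assert by_pos.scores["b"] == pytest.approx(0.9)
        assert by_id.scores["b"] == pytest.approx(0.6)


class TestCommonInvariants:
    @pytest.mark.parametrize("method", ["A", "B", "C"])
    def test_propagated_monotone_root_stripped(self, forked, method):
        db = make_db(("s1", ["c"]), ("s2", ["f"]), ("s3", ["c", "f"]))
        hits = make_hits("q", ("s1", 1e-5, 85.0), ("s2", 1e-4, 70.0),
                         ("s3", 1e-3, 95.0))
        fn = {"A": predict_student_a, "B": predict_student_b,
              "C": predict_student_c}[method]
        pred = fn(hits, db, forked)
        assert forked.root not in pred.scores
        assert all(0.0 <= s <= 1.0 for s in pred.scores.values())
        for child, parent in forked.graph.edges():
            if child in pred.scores and parent in pred.scores:
                assert pred.scores[parent] >= pred.scores[child]
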