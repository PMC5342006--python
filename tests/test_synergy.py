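"""IHC dichotomization, pair enumeration, Fisher synergy screen, 2-hop rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, kstest

from slsift.cohort import CohortSpec, SynergyEffect, generate_ihc_clinical
from slsift.synergy import (
    MarkerDef,
    classify_synergy,
    dedupe_pairs,
    dichotomize_feature,
    dichotomize_marker,
    enumerate_pairs,
    fisher_exact_2x2,
    grade_rank,
    synergy_screen,
    twohop_candidates,
)


class TestMarkerDichotomization:
    def test_grade_scale_order(self):
        ranks = [grade_rank(g) for g in ("0", "±", "1+", "2+", "3+")]
        assert ranks == sorted(ranks) and len(set(ranks)) == 5

    @pytest.mark.parametrize(
        "criterion,grade,expected",
        [
            (">=1+", "1+", True),   # RAD54B(N)-style threshold, boundary inclusive
            (">=1+", "±", False),
            ("<1+", "1+", False),   # BRCA1(C)-style under-expression criterion
            ("<1+", "±", True),
            ("<2+", "3+", False),
            (">=2+", "3+", True),
        ],
    )
    def test_intensity_criteria(self, criterion, grade, expected):
        m = MarkerDef.from_criterion("X", "C", criterion)
        assert dichotomize_marker(grade, m) is expected

    def test_percent_criterion_boundary_inclusive(self):
        m = MarkerDef.from_criterion("CDH1", "M", ">=70%")
        assert dichotomize_marker(70.0, m)
        assert not dichotomize_marker(69.9, m)

    def test_unknown_grade_rejected(self):
        m = MarkerDef.from_criterion("X", "C", ">=1+")
        with pytest.raises(ValueError, match="4\\+"):
            dichotomize_marker("4+", m)

    def test_grades_satisfying_partitions_scale(self):
        m = MarkerDef.from_criterion("X", "C", "<2+")
        ab = set(m.grades_satisfying(True))
        no = set(m.grades_satisfying(False))
        assert ab | no == {"0", "±", "1+", "2+", "3+"} and not ab & no


class TestFeatureDichotomization:
    def test_stage_rule(self):
        assert dichotomize_feature({"stage": "IV"}, "stage") is True
        assert dichotomize_feature({"stage": "II"}, "stage") is False

    def test_nodal_rule(self):
        assert dichotomize_feature({"nodal": "N0"}, "nodal") is False
        assert dichotomize_feature({"nodal": "N2"}, "nodal") is True

    def test_grade_rule(self):
        assert dichotomize_feature({"grade": "poor"}, "grade") is True
        assert dichotomize_feature({"grade": "moderate"}, "grade") is False

    def test_survival_censored_early_not_evaluable(self):
        rec = {"survival_months": 20.0, "event": 0}
        assert dichotomize_feature(rec, "survival3y") is None

    def test_survival_death_before_three_years_adverse(self):
        assert dichotomize_feature({"survival_months": 20.0, "event": 1}, "survival3y") is True
        assert dichotomize_feature({"survival_months": 40.0, "event": 1}, "survival3y") is False

    def test_missing_field_not_evaluable(self):
        assert dichotomize_feature({"stage": None}, "stage") is None

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_feature({}, "smoking")


class TestEnumeratePairs:
    def test_two_distinct_proteins(self):
        panel = [MarkerDef("A", "C", "intensity", ">=", "1+"),
                 MarkerDef("B", "C", "intensity", ">=", "1+")]
        assert enumerate_pairs(panel) == [("A(C)", "B(C)")]

    def test_same_protein_two_locations_excluded(self):
        panel = [
            MarkerDef("A", "C", "intensity", ">=", "1+"),
            MarkerDef("A", "N", "intensity", ">=", "1+"),
            MarkerDef("B", "C", "intensity", ">=", "1+"),
            MarkerDef("C", "N", "intensity", ">=", "1+"),
        ]
        assert len(enumerate_pairs(panel)) == 5

    def test_default_panel_yields_250(self, panel):
        assert len(enumerate_pairs(panel)) == 250

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("ABCDEFG"), st.sampled_from("CNM")),
                    min_size=2, max_size=10, unique=True))
    def test_count_formula(self, defs):
        """|pairs| = C(m,2) - sum over proteins of C(k_p,2)."""
        panel = [MarkerDef(p, loc, "intensity", ">=", "1+") for p, loc in defs]
        m = len(panel)
        from collections import Counter

        k = Counter(d.protein for d in panel)
        expected = math.comb(m, 2) - sum(math.comb(c, 2) for c in k.values() if c > 1)
        got = enumerate_pairs(panel)
        assert len(got) == expected
        # brute force agreement
        brute = {
            tuple(sorted((a.name, b.name)))
            for a, b in itertools.combinations(panel, 2)
            if a.protein != b.protein
        }
        assert {tuple(sorted(p)) for p in got} == brute


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher by explicit hypergeometric enumeration."""
    n = a + b + c + d
    r, k = a + b, a + c
    support = range(max(0, r + k - n), min(r, k) + 1)
    p_obs = hypergeom.pmf(a, n, r, k)
    return sum(
        hypergeom.pmf(x, n, r, k)
        for x in support
        if hypergeom.pmf(x, n, r, k) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_perfect_separation(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_moderate_table(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_zero_margin_is_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=4)
            p = fisher_exact_2x2(t.reshape(2, 2))
            q = _fisher_oracle(*t)
            assert p == pytest.approx(q, rel=1e-6, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_symmetry(self, cells):
        t = np.array(cells).reshape(2, 2)
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)
        assert fisher_exact_2x2(t.T) == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestClassifySynergy:
    @pytest.mark.parametrize(
        "pp,p1,p2,label",
        [
            (0.016, 0.442, 0.357, "synergistic"),
            (0.003, 0.682, 0.012, "putative"),
            (0.2, 0.5, 0.5, "none"),           # pair not significant
            (0.01, 0.005, 0.5, "none"),        # pair not smaller than both singles
            (0.002, 0.252, 0.002, "none"),     # tie with a single: not strictly smaller
            (0.049, 0.05, 0.05, "synergistic"),  # singles exactly at alpha count as null
        ],
    )
    def test_examples(self, pp, p1, p2, label):
        assert classify_synergy(pp, p1, p2) == label

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    def test_partition(self, pp, p1, p2):
        """Every triple gets exactly one of the three labels."""
        assert classify_synergy(pp, p1, p2) in ("synergistic", "putative", "none")


class TestPublishedRows:
    def test_dedup_yields_24_pairs(self, synergy_rows):
        assert len(dedupe_pairs(synergy_rows)) == 24

    def test_every_row_pair_significant(self, synergy_rows):
        assert (synergy_rows["p_pair"] < 0.05).all()


class TestTwoHop:
    def test_transitive_example(self):
        out = twohop_candidates({("PARP1", "BRCA1"), ("BRCA1", "TP53")})
        assert out == [("PARP1", "TP53")]

    def test_second_example(self):
        out = twohop_candidates({("CSNK1E", "TP53"), ("TP53", "RB1")})
        assert out == [("CSNK1E", "RB1")]

    def test_empty_and_singleton(self):
        assert twohop_candidates(set()) == []
        assert twohop_candidates({("A", "B")}) == []

    def test_known_pairs_not_reproposed(self):
        out = twohop_candidates({("A", "B"), ("B", "C"), ("A", "C")})
        assert out == []


class TestSynergyScreen:
    def test_planted_pair_detected(self, demo_study):
        records, predicted = synergy_screen(
            demo_study.spec.markers,
            demo_study.ihc,
            demo_study.clinical,
            with_logrank=False,
        )
        hit = predicted[
            (predicted.marker1 == "FEN1(N)") & (predicted.marker2 == "RAD54B(N)")
        ]
        assert len(hit) == 1

    def test_every_record_labelled_once(self, demo_study):
        records, _ = synergy_screen(
            demo_study.spec.markers,
            demo_study.ihc,
            demo_study.clinical,
            with_logrank=False,
        )
        assert set(records["label"]) <= {"synergistic", "putative", "none"}
        assert len(records) == 250 * 5

    def test_null_screen_finds_few_hits(self):
        """With no planted synergy, labelled records are a small minority."""
        markers = [
            MarkerDef("A", "C", "intensity", ">=", "1+"),
            MarkerDef("B", "N", "intensity", ">=", "1+"),
            MarkerDef("C", "C", "intensity", ">=", "2+"),
            MarkerDef("D", "N", "intensity", "<", "1+"),
        ]
        spec = CohortSpec(
            n_patients=131,
            markers=markers,
            marker_rates={m.name: 0.5 for m in markers},
            seed=3,
        )
        ihc, clinical = generate_ihc_clinical(spec)
        records, _ = synergy_screen(markers, ihc, clinical, with_logrank=False)
        assert (records["label"] != "none").mean() < 0.25


class TestInteractionOnlyPlanting:
    def test_single_marker_pvalues_uniform_under_interaction_only(self):
        """Planting a pair-only effect leaves single-marker tests null.

        Single-marker Fisher p-values over repeated cohorts pass a KS test
        against Uniform(0,1) at alpha=0.01 (mid-p used to de-discretize).
        """
        m1 = MarkerDef("AAA", "N", "intensity", ">=", "1+")
        m2 = MarkerDef("BBB", "N", "intensity", ">=", "1+")
        pvals = []
        for seed in range(300):
            spec = CohortSpec(
                n_patients=131,
                markers=[m1, m2],
                marker_rates={"AAA(N)": 0.5, "BBB(N)": 0.5},
                synergy_effects=[SynergyEffect("AAA(N)", "BBB(N)", "metastasis", 6.0)],
                seed=seed,
            )
            ihc, cl = generate_ihc_clinical(spec)
            a1 = ihc["AAA(N)"].map(m1.is_abnormal).to_numpy()
            y = cl["metastasis"].eq("yes").to_numpy()
            table = np.array(
                [[np.sum(a1 & y), np.sum(a1 & ~y)], [np.sum(~a1 & y), np.sum(~a1 & ~y)]]
            )
            pvals.append(fisher_exact_2x2(table))
        # exact Fisher p-values are discrete and stochastically >= uniform;
        # test one-sided for anti-conservative leakage of the pair effect
        stat, ks_p = kstest(pvals, "uniform", alternative="greater")
        assert ks_p > 0.01
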