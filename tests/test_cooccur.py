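import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from clonehier import cooccur
from clonehier.cohort_model import ValidationError
from clonehier.cooccur import (
    bh_adjust,
    fisher_2x2,
    hma_association,
    lesion_correlation,
    load_table2_counts,
    pair_tables,
    phenotype_or,
)


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    @pytest.mark.parametrize("table,exp_or,exp_p", [
        ((3, 0, 0, 3), math.inf, 0.1),        # 2/20 over the margin-fixed tables
        ((2, 0, 0, 2), math.inf, 1 / 3),
        ((23, 40, 86, 1660), 11.1, None),     # dominant EZH2 → secondary RUNX1
        ((125, 222, 133, 1329), 5.6, None),   # dominant TET2 → secondary TET2
    ])
    def test_reference_tables(self, table, exp_or, exp_p):
        orr, p = fisher_2x2(*table)
        if math.isinf(exp_or):
            assert math.isinf(orr)
        else:
            assert round(orr, 1) == exp_or
        if exp_p is not None:
            assert p == pytest.approx(exp_p, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_2x2(0, 0, 0, 0)

    def test_zero_product_conventions(self):
        assert math.isinf(cooccur.cross_product_or(5, 0, 0, 5))
        assert math.isnan(cooccur.cross_product_or(0, 0, 3, 3))

    @settings(max_examples=250, derandomize=True)
    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30))
           .filter(lambda t: 0 < sum(t) <= 60))
    def test_matches_enumeration_oracle(self, table):
        _, p = fisher_2x2(*table)
        assert p == pytest.approx(fisher_oracle(*table), rel=1e-7, abs=1e-12)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_respects_rank(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    def test_permutation_invariant(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q = bh_adjust(ps)
        q_perm = bh_adjust([ps[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm)


def _labels_from_sets(n, dom_sets, sec_sets):
    rows = []
    for g, pats in dom_sets.items():
        rows += [(f"P{i}", g, "dominant") for i in pats]
    for g, pats in sec_sets.items():
        rows += [(f"P{i}", g, "secondary") for i in pats]
    rows += [(f"P{i}", "FILLER", "dominant") for i in range(n)]
    return pd.DataFrame(rows, columns=["patient_id", "gene", "label"])


class TestPairTables:
    def test_perfect_association(self):
        lab = _labels_from_sets(200, {"X": range(20)}, {"Y": range(20)})
        out = pair_tables(lab, min_freq=0.01)
        row = out[(out["label_a"] == "X") & (out["label_b"] == "Y")].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (20, 0, 0, 180)
        assert math.isinf(row["odds_ratio"])
        assert row["direction"] == "co_occurrence"
        assert row["significant"]

    def test_total_equals_cohort_size(self):
        lab = _labels_from_sets(150, {"X": range(10)}, {"Y": range(5, 25)})
        out = pair_tables(lab, min_freq=0.01)
        assert ((out["a"] + out["b"] + out["c"] + out["d"]) == 150).all()

    def test_min_freq_strict(self):
        # gene dominant in exactly 1% of patients is NOT tested (> is strict)
        lab = _labels_from_sets(100, {"X": range(1)}, {"Y": range(20)})
        out = pair_tables(lab, min_freq=0.01)
        assert "X" not in set(out["label_a"])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pair_tables(pd.DataFrame(columns=["patient_id", "gene", "label"]))

    def test_table2_fixture_reproduced(self):
        """Every printed pair OR is reproduced at 1 d.p. by the cross-product
        or the conditional-MLE estimator (the table mixes the two rounding
        conventions); ME direction matches the sign of the association."""
        t2 = load_table2_counts()
        for row in t2.itertuples():
            counts = (row.co_occurrence, row.dominant_only,
                      row.secondary_only, row.intact)
            assert sum(counts) == 1809
            orr, _ = fisher_2x2(*counts)
            orr_cmle, _ = fisher_2x2(*counts, or_estimator="cmle")
            printed = float(row.or_printed)
            if math.isinf(printed):
                # a = 0 rows: printed as Infinity, cross-product is 0 — the
                # direction (mutual exclusivity) is the reproducible part
                assert row.co_occurrence == 0
                assert row.direction == "ME"
                continue
            assert round(orr, 1) == printed or round(orr_cmle, 1) == printed
            expected_dir = "CO" if orr > 1 else "ME"
            assert expected_dir == row.direction


class TestLesionCorrelation:
    def test_disjoint_lesions_flagged_exclusive(self):
        n = 500
        presence = pd.DataFrame({
            "A": [i < 150 for i in range(n)],
            "B": [150 <= i < 300 for i in range(n)],
        })
        out = lesion_correlation(presence, min_freq=0.02)
        row = out.iloc[0]
        assert row["direction"] == "mutual_exclusivity"
        assert row["significant"]          # q < 0.25 for exclusion

    def test_rare_lesion_not_tested(self):
        n = 200
        presence = pd.DataFrame({
            "COMMON1": [i < 60 for i in range(n)],
            "COMMON2": [i % 3 == 0 for i in range(n)],
            "RARE": [i < 4 for i in range(n)],     # exactly 2% — strict cut
        })
        out = lesion_correlation(presence, min_freq=0.02)
        assert "RARE" not in set(out["label_a"]) | set(out["label_b"])


class TestPhenotypeOr:
    def _clinical(self, n, mpn_ids):
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "diagnosis": ["MDS_MPN" if i in mpn_ids else "MDS" for i in range(n)],
            "ipssr_score": [2.0] * n,
            "risk_group": ["low"] * n,
            "os_months": 10.0, "os_event": False,
            "hma_treated": False, "hma_response": "NA",
        })

    def test_null_group_near_unity(self):
        rng = np.random.default_rng(0)
        n = 1000
        mpn = set(np.flatnonzero(rng.random(n) < 0.3).tolist())
        lab = _labels_from_sets(n, {"X": range(0, n, 5)}, {"Y": range(0, n, 7)})
        out = phenotype_or(lab, self._clinical(n, mpn), grouping="single_lesion")
        row = out[(out["label_a"] == "X") & (out["label_b"] == "MDS_vs_MDSMPN")].iloc[0]
        assert 0.6 < row["odds_ratio"] < 1.6
        assert row["q"] > 0.1

    def test_pair_both_vs_neither_drops_partials(self):
        n = 100
        lab = _labels_from_sets(n, {"X": range(30)}, {"Y": range(20, 50)})
        clin = self._clinical(n, set(range(0, 100, 2)))
        out = phenotype_or(lab, clin, grouping="pair_both_vs_neither")
        row = out[out["label_a"] == "X>Y"].iloc[0]
        # both = 10 (20..29), neither = 50 (50..99); partials 0..19 & 30..49 dropped
        assert row["a"] + row["b"] == 10
        assert row["c"] + row["d"] == 50

    def test_degenerate_pair_flagged_non_estimable(self):
        n = 60
        lab = _labels_from_sets(n, {"X": range(10)}, {"Y": range(10, 20)})
        out = phenotype_or(lab, self._clinical(n, set(range(5))),
                           grouping="pair_both_vs_neither")
        row = out[out["label_a"] == "X>Y"].iloc[0]
        assert not row["estimable"]

    def test_missing_phenotype_rejected(self):
        lab = _labels_from_sets(10, {}, {})
        with pytest.raises(ValidationError):
            phenotype_or(lab, pd.DataFrame({"patient_id": ["P0"]}))


class TestHMA:
    def _clinical(self, responses):
        rows = []
        for i, resp in enumerate(responses):
            rows.append((f"P{i}", "MDS", 2.0, 10.0, False,
                         resp is not None, resp if resp is not None else "NA"))
        return pd.DataFrame(rows, columns=["patient_id", "diagnosis", "ipssr_score",
                                           "os_months", "os_event", "hma_treated",
                                           "hma_response"])

    def test_responder_definition(self):
        clin = self._clinical(["CR", "PR", "HI", "none", None])
        lab = pd.DataFrame({"patient_id": ["P0", "P1", "P3"], "gene": "TET2",
                            "label": "dominant"})
        out = hma_association(clin, lab, groupings=("single_lesion",))
        row = out[(out["label_a"] == "TET2") & (out["label_b"] == "responder")].iloc[0]
        # carriers among 4 treated: P0 (CR), P1 (PR) respond, P3 (none) does not
        assert (row["a"], row["b"], row["c"], row["d"]) == (2, 1, 1, 0)

    def test_no_treated_patients_rejected(self):
        clin = self._clinical([None, None])
        with pytest.raises(ValidationError):
            hma_association(clin, pd.DataFrame(columns=["patient_id", "gene", "label"]))
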