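"""Binomial false-positive model, q-values, candidate calling, hotspot filters."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthet import (
    CallerConfig,
    ReferenceSequence,
    ReferenceSet,
    binomial_false_positive,
    call_candidates,
    finalize_calls,
    flag_hotspots,
    min_coverage_for_significance,
    storey_qvalues,
)


def exact_pmf(n: int, k: int, p: Fraction) -> Fraction:
    """Big-rational binomial point mass: the independent oracle."""
    return comb(n, k) * p**k * (1 - p) ** (n - k)


class TestBinomialFalsePositive:
    def test_single_trial_closed_form(self):
        assert binomial_false_positive(1, 1, 0.005) == pytest.approx(0.005)

    def test_symmetric_closed_form(self):
        assert binomial_false_positive(2, 1, 0.5) == pytest.approx(0.5)

    def test_depth_200_k3(self):
        # exact value: C(200,3) * 0.005^3 * 0.995^197
        expected = float(exact_pmf(200, 3, Fraction(1, 200)))
        got = binomial_false_positive(200, 3, 0.005)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.0612, abs=5e-5)

    @pytest.mark.parametrize("p_frac", [Fraction(1, 200), Fraction(1, 20)])
    @pytest.mark.parametrize("n", [1, 2, 3, 7, 25, 100])
    def test_agrees_with_big_rational_oracle(self, n, p_frac):
        p = float(p_frac)
        ks = np.arange(n + 1)
        got = binomial_false_positive(np.full(n + 1, n), ks, p)
        pmf = Fraction(0)
        ratio = p_frac / (1 - p_frac)
        pmf = (1 - p_frac) ** n
        for k in range(n + 1):
            assert got[k] == pytest.approx(float(pmf), rel=1e-10)
            pmf = pmf * (n - k) * ratio / (k + 1) if k < n else pmf

    @pytest.mark.parametrize("n", [1, 7, 50, 200])
    def test_pmf_sums_to_one(self, n):
        ks = np.arange(n + 1)
        total = binomial_false_positive(np.full(n + 1, n), ks, 0.005).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_tail_mode_is_cumulative_pmf(self):
        n, p = 60, 0.005
        for k in [0, 1, 3, 10]:
            tail = binomial_false_positive(n, k, p, mode="tail")
            summed = sum(binomial_false_positive(n, j, p) for j in range(k, n + 1))
            assert tail == pytest.approx(summed, rel=1e-9)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_false_positive(5, 6, 0.005)

    def test_coverage_cutoff_decreases_with_frequency_threshold(self):
        """Higher detection thresholds reach significance at lower coverage."""
        cutoffs = [
            min_coverage_for_significance(f, p=0.005, pf_max=0.01)
            for f in (0.010, 0.015, 0.030, 0.050)
        ]
        assert cutoffs == sorted(cutoffs, reverse=True)
        assert cutoffs[0] > cutoffs[-1]


class TestStoreyQvalues:
    def test_single_p_identity(self):
        assert storey_qvalues([0.2], pi0=1.0).tolist() == [0.2]

    def test_step_up_example(self):
        q = storey_qvalues([0.01, 0.02, 0.04], pi0=1.0)
        assert q == pytest.approx([0.03, 0.03, 0.04])

    def test_scales_linearly_in_pi0(self):
        q1 = storey_qvalues([0.01, 0.02, 0.04], pi0=1.0)
        q005 = storey_qvalues([0.01, 0.02, 0.04], pi0=0.05)
        assert q005 == pytest.approx(0.05 * q1)

    def test_empty_input(self):
        assert storey_qvalues([], pi0=0.05).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_matches_double_loop_oracle(self, pvals, pi0):
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        expected = [None] * m
        for rank_i, idx in enumerate(order, start=1):
            expected[idx] = min(
                pi0 * m * pvals[order[j - 1]] / j for j in range(rank_i, m + 1)
            )
        got = storey_qvalues(pvals, pi0=pi0)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_bounds_and_monotonicity(self, pvals):
        pi0 = 0.3
        m = len(pvals)
        q = storey_qvalues(pvals, pi0=pi0)
        ranks = np.empty(m, dtype=int)
        order = np.argsort(np.asarray(pvals), kind="stable")
        ranks[order] = np.arange(1, m + 1)
        assert (q <= pi0 * m * np.asarray(pvals) / ranks + 1e-15).all()
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= pi0 * max(pvals) + 1e-15).all()


def site(chrom="c", pos=1, ref="A", **counts):
    row = {"chrom": chrom, "pos": pos, "ref": ref, "A": 0, "C": 0, "G": 0, "T": 0}
    row.update(counts)
    return row


class TestCallCandidates:
    def test_minor_allele_above_threshold(self):
        table = pd.DataFrame([site(pos=1, A=5900, G=100)])
        cands = call_candidates(table, sample="s")
        assert len(cands) == 1
        row = cands.iloc[0]
        assert (row.variant, row.k, row.n) == ("G", 100, 6000)
        assert row.freq == pytest.approx(100 / 6000)
        assert not row.multi_allelic

    def test_strict_inequality_boundary(self):
        table = pd.DataFrame([site(pos=1, A=5910, G=90)])  # 90/6000 == 0.015 exactly
        assert call_candidates(table).empty

    def test_multiallelic_represented_by_highest_count_alt(self):
        table = pd.DataFrame([site(pos=1, A=5785, G=120, T=95)])
        cands = call_candidates(table)
        assert len(cands) == 1
        assert cands.iloc[0].variant == "G" and cands.iloc[0].multi_allelic

    def test_alphabetical_tie_break(self):
        table = pd.DataFrame([site(pos=1, A=5800, G=100, T=100)])
        assert call_candidates(table).iloc[0].variant == "G"

    def test_zero_depth_skipped(self):
        table = pd.DataFrame([site(pos=1)])
        assert call_candidates(table).empty


class TestHotspots:
    @pytest.fixture()
    def reference(self):
        #            123456789012345678901234
        seq_linear = "GGCTAAAACTTGCATGCATGCATG"
        return ReferenceSet([ReferenceSequence("lin", seq_linear, "linear")])

    def _calls(self, rows):
        return pd.DataFrame(
            [
                {"sample": "s", "chrom": c, "pos": p, "consensus": "C", "variant": "T",
                 "k": 100, "n": 6000, "freq": 100 / 6000, "multi_allelic": False}
                for c, p in rows
            ]
        )

    def test_four_base_run_flags_following_site(self, reference):
        # positions 5-8 are AAAA; position 9 is immediately 3' of the run
        flagged = flag_hotspots(self._calls([("lin", 9)]), reference)
        assert flagged["hotspot_homopolymer"].iloc[0]

    def test_run_of_three_does_not_flag(self, reference):
        # site 8 has only AAA (5-7) behind it on the 5' side, CTT ahead
        flagged = flag_hotspots(self._calls([("lin", 8)]), reference)
        assert not flagged["hotspot_homopolymer"].iloc[0]

    def test_downstream_run_flags_via_reverse_strand(self, reference):
        # position 4 precedes AAAA (5-8): the run is 5' of the site on the minus strand
        flagged = flag_hotspots(self._calls([("lin", 4)]), reference)
        assert flagged["hotspot_homopolymer"].iloc[0]

    def test_circular_wraparound_run(self):
        ref = ReferenceSet([ReferenceSequence("circ", "AAGCATGCATGCATGCATAA", "circular")])
        # 5' context of position 3 wraps: positions 19,20,1,2 = A,A,A,A
        flagged = flag_hotspots(self._calls([("circ", 3)]), ref)
        assert flagged["hotspot_homopolymer"].iloc[0]

    def test_linear_edge_checks_only_available_side(self, reference):
        flagged = flag_hotspots(self._calls([("lin", 2)]), reference)
        assert not flagged["hotspot_homopolymer"].iloc[0]

    def test_adjacent_sites_both_flagged(self, reference):
        flagged = flag_hotspots(self._calls([("lin", 15), ("lin", 16), ("lin", 20)]), reference)
        assert flagged["hotspot_adjacent"].tolist() == [True, True, False]

    def test_adjacency_requires_same_sample(self, reference):
        calls = self._calls([("lin", 15), ("lin", 16)])
        calls.loc[1, "sample"] = "other"
        flagged = flag_hotspots(calls, reference)
        assert flagged["hotspot_adjacent"].tolist() == [False, False]


class TestFinalizeCalls:
    def _candidates(self, rows):
        return pd.DataFrame(rows)

    def _cand(self, pos=1, k=100, n=6000, chrom="c", sample="s"):
        return {"sample": sample, "chrom": chrom, "pos": pos, "consensus": "A",
                "variant": "G", "k": k, "n": n, "freq": k / n, "multi_allelic": False}

    def test_pf_threshold(self):
        # freq 2% passes the frequency gate but P_f(pmf) is far above 1%
        cands = self._candidates([self._cand(k=2, n=100)])
        calls, attrition = finalize_calls(cands)
        assert calls["status"].iloc[0] == "fail_pf"
        assert attrition["fail_pf"] == 1 and attrition["pass"] == 0

    def test_clean_candidate_passes(self):
        cands = self._candidates([self._cand(k=120, n=6000)])
        calls, attrition = finalize_calls(cands)
        assert calls["status"].iloc[0] == "pass" and attrition["pass"] == 1

    def test_hotspot_overrides_pass(self):
        ref = ReferenceSet([ReferenceSequence("c", "GGCTAAAACTTGCATG", "linear")])
        cands = self._candidates([self._cand(pos=9, k=120, n=6000)])
        calls, attrition = finalize_calls(cands, reference=ref)
        assert calls["status"].iloc[0] == "fail_hotspot"
        assert attrition["fail_hotspot"] == 1

    def test_hotspot_filter_can_be_disabled(self):
        ref = ReferenceSet([ReferenceSequence("c", "GGCTAAAACTTGCATG", "linear")])
        cfg = CallerConfig(apply_hotspot_filter=False)
        calls, _ = finalize_calls(self._candidates([self._cand(pos=9, k=120, n=6000)]),
                                  cfg, reference=ref)
        assert calls["status"].iloc[0] == "pass"
        assert calls["hotspot_homopolymer"].iloc[0]  # flag still reported

    def test_frequency_failure_takes_precedence(self):
        cands = self._candidates([self._cand(k=60, n=6000)])  # freq 1% <= 1.5%
        calls, _ = finalize_calls(cands)
        assert calls["status"].iloc[0] == "fail_freq"

    def test_qvalues_computed_per_sample(self):
        rows = [self._cand(pos=p, k=120, n=6000, sample="a") for p in (10, 20, 30)]
        rows += [self._cand(pos=p, k=120, n=6000, sample="b") for p in (10, 50)]
        calls, _ = finalize_calls(self._candidates(rows))
        for sample, group in calls.groupby("sample"):
            expected = storey_qvalues(group["p_f"].to_numpy(), pi0=0.05)
            assert group["q_f"].to_numpy() == pytest.approx(expected)

    def test_no_pass_call_at_or_below_min_freq(self, louse_run):
        _, _, _, _, results = louse_run
        cfg = CallerConfig()
        passed = results.passed
        assert (passed["freq"] > cfg.min_freq).all()
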