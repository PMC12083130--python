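import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dvtpipe import enrich


def brute_force_upper_tail(k, K, n, N):
    """Definitional oracle: sum the hypergeometric pmf over j >= k."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
    return total


def bh_step_up_oracle(pvals):
    """Textbook BH: q_(i) = min over j>=i of p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvals[idx] * m / rank)
        adjusted[idx] = min(1.0, running_min)
    return adjusted


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        assert enrich.hypergeom_upper_tail(0, 5, 5, 10) == 1.0

    def test_single_maximal_draw(self):
        # all 5 query genes land in the 5-member term: 1 / C(10,5)
        assert enrich.hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_matches_pmf_summation(self):
        assert enrich.hypergeom_upper_tail(4, 6, 8, 20) == pytest.approx(
            brute_force_upper_tail(4, 6, 8, 20)
        )

    def test_bounds_violation_raises(self):
        with pytest.raises(ValueError):
            enrich.hypergeom_upper_tail(7, 6, 8, 20)
        with pytest.raises(ValueError):
            enrich.hypergeom_upper_tail(1, 25, 8, 20)

    @given(st.integers(1, 25))
    def test_nonincreasing_in_k(self, N):
        K, n = max(1, N // 2), max(1, N // 3)
        tails = [enrich.hypergeom_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


class TestEnrichmentRatio:
    def test_null_expectation_gives_one(self):
        assert enrich.enrichment_ratio(3, 6, 10, 20) == pytest.approx(1.0)

    def test_zero_overlap_gives_zero(self):
        assert enrich.enrichment_ratio(0, 6, 10, 20) == 0.0

    def test_direct_arithmetic(self):
        assert enrich.enrichment_ratio(4, 6, 8, 20) == pytest.approx((4 / 8) / (6 / 20))

    def test_undefined_expectation_reported_missing(self):
        assert enrich.enrichment_ratio(0, 0, 10, 20) is None


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert enrich.bh_adjust([0.04]) == [pytest.approx(0.04)]

    def test_hand_worked_step_up(self):
        assert enrich.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_definitional_oracle_on_random_vector(self):
        rng = np.random.default_rng(21)
        pvals = rng.uniform(1e-6, 1.0, size=50).tolist()
        assert enrich.bh_adjust(pvals) == pytest.approx(bh_step_up_oracle(pvals))

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
    def test_adjusted_at_least_raw_and_order_preserved(self, pvals):
        adjusted = enrich.bh_adjust(pvals)
        assert len(adjusted) == len(pvals)
        assert all(q >= p - 1e-12 and q <= 1.0 for p, q in zip(pvals, adjusted))

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60),
           st.floats(0.01, 0.2))
    def test_rejection_set_equals_classical_step_up(self, pvals, alpha):
        adjusted = enrich.bh_adjust(pvals)
        by_q = {i for i, q in enumerate(adjusted) if q <= alpha}
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        cutoff = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= alpha * rank / m:
                cutoff = rank
        classical = set(order[:cutoff])
        assert by_q == classical

    def test_out_of_domain_pvalues_rejected(self):
        with pytest.raises(ValueError):
            enrich.bh_adjust([0.0, 0.5])


def term(term_id, members, name=None, namespace="BP"):
    return enrich.GeneSetTerm(term_id, name or term_id, namespace, frozenset(members))


class TestEnrich:
    def test_perfect_enrichment_ranks_first(self):
        target = term("T1", {"A", "B", "C"})
        filler = term("T2", {f"X{i}" for i in range(40)})
        results = enrich.enrich({"A", "B", "C"}, [target, filler])
        assert results[0].term_id == "T1"
        assert results[0].k == 3
        assert results[0].q <= 0.05

    def test_disjoint_query_gives_p_one_everywhere(self):
        terms = [term("T1", {"A", "B"}), term("T2", {"C", "D"})]
        results = enrich.enrich({"E"}, terms, universe={"A", "B", "C", "D", "E"}, min_overlap=0)
        assert all(r.k == 0 and r.p == 1.0 for r in results)

    def test_min_overlap_excludes_terms_from_bh_family(self):
        target = term("T1", {"A", "B"})
        singleton = term("T2", {"A"} | {f"X{i}" for i in range(5)})
        results = enrich.enrich({"A", "B"}, [target, singleton])
        assert [r.term_id for r in results] == ["T1"]

    def test_empty_universe_is_config_error(self):
        with pytest.raises(ValueError):
            enrich.enrich({"A"}, [term("T1", {"A"})], universe=[])

    def test_permutation_invariance_of_term_order(self):
        terms = [term(f"T{i}", {f"G{j}" for j in range(i, i + 6)}) for i in range(8)]
        query = {f"G{j}" for j in range(0, 12)}
        forward = enrich.enrich(query, terms)
        backward = enrich.enrich(query, terms[::-1])
        assert [(r.term_id, r.p, r.q) for r in forward] == [(r.term_id, r.p, r.q) for r in backward]

    def test_query_outside_universe_dropped_from_test(self):
        results = enrich.enrich({"A", "ZZZ"}, [term("T1", {"A", "B"})], min_overlap=1)
        assert results[0].n == 1  # only A is in the annotated universe


class TestGenesInTerms:
    def test_no_significant_terms_yields_empty(self):
        t = term("T1", {"A", "B"})
        results = [enrich.EnrichmentResult("T1", "T1", 2, 2, 2, 4, 1.0, 0.5, q=0.5)]
        assert enrich.genes_in_terms({"A", "B"}, results, [t], lambda n: True) == set()

    def test_significant_term_containing_query_returns_query(self):
        t = term("T1", {"A", "B", "C"})
        results = [enrich.EnrichmentResult("T1", "T1", 2, 3, 2, 40, 10.0, 1e-4, q=1e-4)]
        assert enrich.genes_in_terms({"A", "B"}, results, [t], lambda n: True) == {"A", "B"}

    def test_term_filter_restricts_union(self):
        t1 = term("T1", {"A"}, name="coagulation")
        t2 = term("T2", {"B"}, name="axon guidance")
        results = [
            enrich.EnrichmentResult("T1", "coagulation", 1, 1, 2, 40, 20.0, 1e-4, q=1e-4),
            enrich.EnrichmentResult("T2", "axon guidance", 1, 1, 2, 40, 20.0, 1e-4, q=1e-4),
        ]
        got = enrich.genes_in_terms(
            {"A", "B"}, results, [t1, t2], enrich.name_filter(["Coagulation"])
        )
        assert got == {"A"}


def test_gmt_round_trip(tmp_path):
    terms = [
        term("GO:1", {"A", "B"}, name="first process"),
        term("GO:2", {"C"}, name="second process"),
    ]
    path = tmp_path / "sets.gmt"
    enrich.write_gmt(terms, path)
    back = enrich.read_gmt(path, "BP")
    assert [(t.term_id, t.name, t.members) for t in back] == [
        (t.term_id, t.name, t.members) for t in terms
    ]


def test_gmt_reader_skips_malformed_and_duplicate_lines(tmp_path):
    path = tmp_path / "odd.gmt"
    path.write_text("# comment\nGO:1\tname\tA\tB\nshort\tline\nGO:1\tdup\tC\n")
    terms = enrich.read_gmt(path, "BP")
    assert len(terms) == 1 and terms[0].members == frozenset({"A", "B"})
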