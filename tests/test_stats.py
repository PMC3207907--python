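"""Exact hypergeometric / Fisher statistics against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from motiflink.stats import (ContingencyTable, EnrichmentResult,
                             fisher_one_tailed, hypergeom_log_pmf,
                             hypergeom_upper_tail, log_binomial,
                             overrepresentation_report, report_text)
from motiflink.pairs import GeneCallTable


def pascal_binomial(n, k):
    """Exact integer C(n, k) by Pascal's recurrence (oracle)."""
    row = [1]
    for _ in range(n):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    return row[k]


def enumerate_upper_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) samples."""
    positives = set(range(K))
    total = hits = 0
    for sample in combinations(range(N), n):
        total += 1
        if len(positives.intersection(sample)) >= k:
            hits += 1
    return hits / total


class TestLogBinomial:
    @pytest.mark.parametrize("n,k", [(25, 11), (5, 2), (40, 20), (17, 0), (9, 9)])
    def test_matches_pascal_recurrence_to_10_digits(self, n, k):
        exact = math.log(pascal_binomial(n, k))
        assert log_binomial(n, k) == pytest.approx(exact, rel=1e-11)

    def test_known_value(self):
        assert log_binomial(25, 11) == pytest.approx(math.log(4_457_400), rel=1e-12)

    @pytest.mark.parametrize("n,k", [(5, 6), (-1, 0), (5, -1)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            log_binomial(n, k)


class TestHypergeomUpperTail:
    def test_exhaustive_enumeration_small(self):
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)
        for k in range(6):
            assert hypergeom_upper_tail(10, 5, 5, k) == \
                pytest.approx(enumerate_upper_tail(10, 5, 5, k), rel=1e-10)

    def test_k_zero_is_total_probability(self):
        assert hypergeom_upper_tail(100, 30, 10, 0) == 1.0
        assert hypergeom_upper_tail(7, 2, 3, 0) == 1.0

    def test_agrees_with_scipy_survival_function(self):
        for (N, K, n, k) in [(25, 8, 11, 6), (32_120, 500, 11, 6),
                             (1000, 100, 50, 12)]:
            assert hypergeom_upper_tail(N, K, n, k) == \
                pytest.approx(sps.hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    def test_pmf_normalizes_at_genome_scale(self):
        """Support sums to 1 within 1e-12 even for N in the ten-thousands."""
        for (N, K, n) in [(10_000, 400, 120), (32_120, 1_000, 25), (50, 20, 9)]:
            lo, hi = max(0, n - (N - K)), min(K, n)
            total = sum(np.exp(hypergeom_log_pmf(N, K, n, i))
                        for i in range(lo, hi + 1))
            assert abs(total - 1.0) < 1e-12

    def test_tail_non_increasing_in_k(self):
        N, K, n = 200, 40, 30
        tails = [hypergeom_upper_tail(N, K, n, k) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_domain_violation(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 20, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 5, 6)


class TestFisherOneTailed:
    def test_screened_gene_sets_worked_example(self):
        """6/11 positives vs 2/14 gives one-tailed p = 0.043 (0.0433 exact)."""
        p = fisher_one_tailed(ContingencyTable(a=6, b=5, c=2, d=12))
        assert p == pytest.approx(192_984 / 4_457_400, rel=1e-12)
        assert round(p, 3) == 0.043

    def test_no_positives_gives_1(self):
        assert fisher_one_tailed(ContingencyTable(0, 5, 0, 5)) == 1.0

    def test_extreme_table(self):
        assert fisher_one_tailed(ContingencyTable(5, 0, 0, 5)) == \
            pytest.approx(1 / 252, rel=1e-12)

    def test_exhaustive_fixed_margin_enumeration(self):
        """Agreement with direct enumeration of all tables at fixed margins."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            n1 = int(rng.integers(1, 20))
            n2 = int(rng.integers(1, 41 - n1))
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            t = ContingencyTable(a, n1 - a, c, n2 - c)
            K = a + c
            # enumerate every table with the same margins; sum the
            # probabilities of those at least as enriched in set 1
            num = den = 0.0
            for a2 in range(max(0, K - n2), min(K, n1) + 1):
                w = (pascal_binomial(n1, a2) * pascal_binomial(n2, K - a2))
                den += w
                if a2 >= a:
                    num += w
            assert fisher_one_tailed(t) == pytest.approx(num / den, rel=1e-9)

    def test_agrees_with_scipy_greater_alternative(self):
        for (a, b, c, d) in [(6, 5, 2, 12), (3, 7, 5, 5), (0, 9, 4, 6)]:
            _, p_ref = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert fisher_one_tailed(ContingencyTable(a, b, c, d)) == \
                pytest.approx(p_ref, rel=1e-9)

    def test_directionality(self):
        enriched = fisher_one_tailed(ContingencyTable(9, 1, 1, 9))
        depleted = fisher_one_tailed(ContingencyTable(1, 9, 9, 1))
        assert enriched < 0.01 < depleted

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


def make_calls(positives, negatives):
    import pandas as pd
    calls = {g: True for g in positives}
    calls.update({g: False for g in negatives})
    return GeneCallTable(calls=calls, details=pd.DataFrame())


class TestReport:
    def test_counts_and_pairwise_fisher(self):
        hc = [f"h{i}" for i in range(11)]
        pc = [f"p{i}" for i in range(14)]
        calls = make_calls(hc[:6] + pc[:2], hc[6:] + pc[2:])
        per_set, fishers, warnings = overrepresentation_report(
            calls, {"HC": hc, "PC": pc},
            population_size=32_120, population_positives=500)
        assert per_set["HC"].sample_positives == 6
        assert per_set["PC"].sample_positives == 2
        hc_vs_pc = next(f for f in fishers if f.set1 == "HC")
        assert hc_vs_pc.p_one_tailed == pytest.approx(0.0433, abs=5e-4)
        assert not warnings
        text = report_text(per_set, fishers, warnings)
        assert "No multiple-testing correction" in text

    def test_unknown_genes_warned_and_excluded(self):
        calls = make_calls(["a"], ["b", "c"])
        per_set, _, warnings = overrepresentation_report(
            calls, {"S1": ["a", "b", "ghost"], "S2": ["c"]},
            population_size=100, population_positives=10)
        assert warnings == {"S1": ["ghost"]}
        assert per_set["S1"].sample_size == 2

    def test_empty_set_rejected(self):
        calls = make_calls(["a"], [])
        with pytest.raises(ValueError):
            overrepresentation_report(calls, {"S": []}, 10, 1)

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            EnrichmentResult(10, 5, 5, 6, 0.5)


def test_null_calibration_super_uniform(rng):
    """Under random assignment of positives, one-tailed p is super-uniform."""
    n1, n2, n_pos, reps = 11, 14, 8, 400
    alpha = 0.05
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(n1 + n2)
        a = int((perm[:n1] < n_pos).sum())
        c = n_pos - a
        p = fisher_one_tailed(ContingencyTable(a, n1 - a, c, n2 - c))
        hits += p <= alpha
    se = math.sqrt(alpha * (1 - alpha) / reps)
    assert hits / reps <= alpha + 3 * se
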