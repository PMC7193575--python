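import itertools
import math

import numpy as np
import pytest

from hlacall.popgen import (
    allele_frequencies,
    em_haplotypes,
    ld_pair,
    ld_test,
)


def tbl(pairs_by_locus):
    """Build a genotype table from per-locus lists of (a1, a2) pairs."""
    loci = list(pairs_by_locus)
    n = len(pairs_by_locus[loci[0]])
    return {
        f"s{i:03d}": {locus: pairs_by_locus[locus][i] for locus in loci}
        for i in range(n)
    }


class TestAlleleFrequencies:
    def test_direct_counting(self):
        pairs = [("A*02:01", "A*02:01")] * 5 + [("A*02:01", "A*03:01")] * 1
        pairs += [("A*01:01", "A*03:01")] * 4
        t = tbl({"A": pairs})
        freqs = allele_frequencies(t, "A", field_level=2)
        assert freqs["A*2:1"] == pytest.approx(11 / 20)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_single_allele(self):
        t = tbl({"A": [("A*01:01", "A*01:01")] * 3})
        assert allele_frequencies(t, "A") == {"A*1:1": 1.0}

    def test_first_field_calls_excluded_by_default(self):
        t = tbl({"A": [("A*01", "A*01:01"), ("A*01:01", None)]})
        freqs = allele_frequencies(t, "A", field_level=2)
        assert freqs == {"A*1:1": 1.0}

    def test_matches_hash_count_oracle(self):
        rng = np.random.default_rng(6)
        alleles = ["A*01:01", "A*02:01", "A*03:01", "A*24:02"]
        pairs = [
            (alleles[int(rng.integers(4))], alleles[int(rng.integers(4))])
            for _ in range(40)
        ]
        t = tbl({"A": pairs})
        counts = {}
        for a, b in pairs:
            for x in (a, b):
                counts[x] = counts.get(x, 0) + 1
        freqs = allele_frequencies(t, "A")
        for name, c in counts.items():
            key = name.replace("*0", "*").replace(":0", ":")
            assert freqs[key] == pytest.approx(c / 80)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            allele_frequencies(tbl({"A": [(None, None)]}), "A")


def grid_search_loglik(genotypes, haplotypes, step=0.005):
    """Exhaustive likelihood maximisation over a frequency grid (oracle)."""
    k = len(haplotypes)
    idx = {h: i for i, h in enumerate(haplotypes)}
    best = (-math.inf, None)
    ticks = int(round(1 / step))
    for combo in itertools.product(range(ticks + 1), repeat=k - 1):
        if sum(combo) > ticks:
            continue
        f = [c * step for c in combo]
        f.append(1 - sum(f))
        ll = 0.0
        for geno in genotypes:
            p = 0.0
            for h1, h2 in geno:
                p += (1 if h1 == h2 else 2) * f[idx[h1]] * f[idx[h2]]
            ll += math.log(p) if p > 0 else -1e9
        if ll > best[0]:
            best = (ll, f)
    return best


class TestEmHaplotypes:
    def test_double_homozygotes_equal_direct_counts(self):
        pairs_a = [("A*01:01", "A*01:01")] * 3 + [("A*02:01", "A*02:01")] * 1
        pairs_b = [("B*07:02", "B*07:02")] * 3 + [("B*08:01", "B*08:01")] * 1
        t = tbl({"A": pairs_a, "B": pairs_b})
        est = em_haplotypes(t, ("A", "B"), seed=0)
        assert est.frequencies[("A*1:1", "B*7:2")] == pytest.approx(0.75, abs=1e-9)
        assert est.frequencies[("A*2:1", "B*8:1")] == pytest.approx(0.25, abs=1e-9)

    def test_single_double_heterozygote_flags_multimodality(self):
        t = tbl({"A": [("A*01:01", "A*02:01")], "B": [("B*07:02", "B*08:01")]})
        est = em_haplotypes(t, ("A", "B"), seed=1)
        assert est.multimodal
        assert sum(est.frequencies.values()) == pytest.approx(1.0)

    def test_matches_grid_search_oracle_on_five_individuals(self):
        pairs_a = [
            ("A*01:01", "A*01:01"),
            ("A*01:01", "A*02:01"),
            ("A*01:01", "A*02:01"),
            ("A*02:01", "A*02:01"),
            ("A*01:01", "A*02:01"),
        ]
        pairs_b = [
            ("B*07:02", "B*07:02"),
            ("B*07:02", "B*08:01"),
            ("B*07:02", "B*07:02"),
            ("B*08:01", "B*08:01"),
            ("B*07:02", "B*08:01"),
        ]
        t = tbl({"A": pairs_a, "B": pairs_b})
        est = em_haplotypes(t, ("A", "B"), seed=2)
        # independent oracle: exhaustive grid over the 4-haplotype simplex
        from hlacall.popgen import _complete_individuals, _expand_configs

        genotypes = [_expand_configs(g) for g in _complete_individuals(t, ("A", "B"), 2)]
        haplotypes = sorted({h for g in genotypes for pair in g for h in pair})
        ll_grid, f_grid = grid_search_loglik(genotypes, haplotypes, step=0.005)
        for h, f in zip(haplotypes, f_grid):
            assert est.frequencies.get(h, 0.0) == pytest.approx(f, abs=1e-3)
        assert est.log_likelihood >= ll_grid - 1e-6

    def test_recovers_known_frequencies_at_large_n(self):
        """Sampling 500 diploids from known haplotype frequencies, EM
        estimates sit within 3 binomial sigma of the truth."""
        rng = np.random.default_rng(11)
        haps = [("A*01:01", "B*07:02"), ("A*01:01", "B*08:01"),
                ("A*02:01", "B*07:02"), ("A*02:01", "B*08:01")]
        true_f = np.array([0.4, 0.1, 0.2, 0.3])
        n = 500
        draws = rng.choice(4, size=(n, 2), p=true_f)
        pairs_a = [(haps[i][0], haps[j][0]) for i, j in draws]
        pairs_b = [(haps[i][1], haps[j][1]) for i, j in draws]
        est = em_haplotypes(tbl({"A": pairs_a, "B": pairs_b}), ("A", "B"), seed=3)
        for h, f in zip(haps, true_f):
            key = tuple(x.replace("*0", "*").replace(":0", ":") for x in h)
            sigma = math.sqrt(f * (1 - f) / (2 * n))
            assert abs(est.frequencies.get(key, 0.0) - f) < 3 * sigma

    def test_three_locus_estimation(self):
        pairs = {
            "A": [("A*01:01", "A*01:01"), ("A*02:01", "A*01:01")] * 3,
            "B": [("B*07:02", "B*07:02"), ("B*08:01", "B*07:02")] * 3,
            "C": [("C*07:01", "C*07:01"), ("C*04:01", "C*07:01")] * 3,
        }
        est = em_haplotypes(tbl(pairs), ("A", "B", "C"), seed=4)
        assert sum(est.frequencies.values()) == pytest.approx(1.0)
        assert est.frequencies[("A*1:1", "B*7:2", "C*7:1")] > 0.5

    def test_no_complete_individuals_raises(self):
        t = tbl({"A": [("A*01:01", None)], "B": [("B*07:02", "B*07:02")]})
        with pytest.raises(ValueError):
            em_haplotypes(t, ("A", "B"))


class TestLdPair:
    def test_perfect_ld_gives_unit_d_prime_and_wn(self):
        pairs_a = [("A*01:01", "A*01:01")] * 4 + [("A*01:01", "A*02:01")] * 8
        pairs_a += [("A*02:01", "A*02:01")] * 4
        pairs_b = [("B*07:02", "B*07:02")] * 4 + [("B*07:02", "B*08:01")] * 8
        pairs_b += [("B*08:01", "B*08:01")] * 4
        # alleles perfectly co-occur: A*01:01 always travels with B*07:02
        res = ld_pair(tbl({"A": pairs_a, "B": pairs_b}), "A", "B")
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)
        assert res.wn == pytest.approx(1.0, abs=1e-6)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(13)
        a_pool = ["A*01:01", "A*02:01"]
        b_pool = ["B*07:02", "B*08:01"]
        pairs_a = [
            (a_pool[int(rng.integers(2))], a_pool[int(rng.integers(2))])
            for _ in range(400)
        ]
        pairs_b = [
            (b_pool[int(rng.integers(2))], b_pool[int(rng.integers(2))])
            for _ in range(400)
        ]
        res = ld_pair(tbl({"A": pairs_a, "B": pairs_b}), "A", "B")
        assert res.d_prime < 0.12
        assert res.wn < 0.12

    def test_chi_square_matches_contingency_oracle(self):
        """With phase-unambiguous data (all double homozygotes) the Wn
        statistic reduces to a textbook chi-square on haplotype counts."""
        from scipy.stats import chi2_contingency

        counts = {  # 3x2 haplotype count table, one individual = 2 copies
            ("A*01:01", "B*07:02"): 8,
            ("A*01:01", "B*08:01"): 2,
            ("A*02:01", "B*07:02"): 3,
            ("A*02:01", "B*08:01"): 7,
            ("A*03:01", "B*07:02"): 5,
            ("A*03:01", "B*08:01"): 5,
        }
        pairs_a, pairs_b = [], []
        for (a, b), n in counts.items():
            pairs_a += [(a, a)] * n
            pairs_b += [(b, b)] * n
        res = ld_pair(tbl({"A": pairs_a, "B": pairs_b}), "A", "B")
        obs = np.array([[8, 2], [3, 7], [5, 5]]) * 2  # 2N haplotypes
        chi2 = chi2_contingency(obs, correction=False).statistic
        expected_wn = math.sqrt(chi2 / (obs.sum() * (min(obs.shape) - 1)))
        assert res.wn == pytest.approx(expected_wn, abs=1e-9)

    def test_relabeling_invariance(self):
        pairs_a = [("A*01:01", "A*02:01")] * 6 + [("A*01:01", "A*01:01")] * 4
        pairs_b = [("B*07:02", "B*08:01")] * 6 + [("B*07:02", "B*07:02")] * 4
        base = ld_pair(tbl({"A": pairs_a, "B": pairs_b}), "A", "B")
        swap = {"A*01:01": "A*33:01", "A*02:01": "A*11:01"}
        pairs_a2 = [(swap[a], swap[b]) for a, b in pairs_a]
        relabeled = ld_pair(tbl({"A": pairs_a2, "B": pairs_b}), "A", "B")
        assert relabeled.d_prime == pytest.approx(base.d_prime, abs=1e-9)
        assert relabeled.wn == pytest.approx(base.wn, abs=1e-9)

    def test_monomorphic_locus_flagged(self):
        t = tbl({"A": [("A*01:01", "A*01:01")] * 5,
                 "B": [("B*07:02", "B*08:01")] * 5})
        res = ld_pair(t, "A", "B")
        assert math.isnan(res.d_prime)
        assert res.note == "monomorphic locus"


class TestLdTest:
    def test_perfect_association_reaches_minimum_p(self):
        pairs_a = [("A*01:01", "A*02:01")] * 10 + [("A*01:01", "A*01:01")] * 10
        pairs_b = [("B*07:02", "B*08:01")] * 10 + [("B*07:02", "B*07:02")] * 10
        res = ld_test(tbl({"A": pairs_a, "B": pairs_b}), "A", "B",
                      n_perm=99, seed=7)
        assert res.p_perm == pytest.approx(1 / 100)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        a_pool = ["A*01:01", "A*02:01"]
        b_pool = ["B*07:02", "B*08:01"]
        pairs_a = [(a_pool[int(rng.integers(2))], a_pool[int(rng.integers(2))])
                   for _ in range(30)]
        pairs_b = [(b_pool[int(rng.integers(2))], b_pool[int(rng.integers(2))])
                   for _ in range(30)]
        t = tbl({"A": pairs_a, "B": pairs_b})
        p1 = ld_test(t, "A", "B", n_perm=49, seed=9).p_perm
        p2 = ld_test(t, "A", "B", n_perm=49, seed=9).p_perm
        assert p1 == p2

    def test_nperm_must_be_positive(self):
        t = tbl({"A": [("A*01:01", "A*02:01")] * 3,
                 "B": [("B*07:02", "B*08:01")] * 3})
        with pytest.raises(ValueError):
            ld_test(t, "A", "B", n_perm=0)


def test_em_loglik_monotone_under_the_hood():
    """The EM iteration asserts monotone likelihood internally; a normal
    run over ambiguous data must complete without tripping it."""
    rng = np.random.default_rng(20)
    a_pool = ["A*01:01", "A*02:01", "A*03:01"]
    b_pool = ["B*07:02", "B*08:01"]
    pairs_a = [(a_pool[int(rng.integers(3))], a_pool[int(rng.integers(3))])
               for _ in range(60)]
    pairs_b = [(b_pool[int(rng.integers(2))], b_pool[int(rng.integers(2))])
               for _ in range(60)]
    est = em_haplotypes(tbl({"A": pairs_a, "B": pairs_b}), ("A", "B"), seed=6)
    assert est.n_iterations >= 1
    assert sum(est.frequencies.values()) == pytest.approx(1.0)
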