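"""Allele frequencies, multiallelic LD and EM haplotype estimation.

Works directly on genotype tables (sample -> locus -> two allele calls).
Following standard practice for HLA cohort statistics, only calls at 2nd
field resolution or better enter the analyses (configurable), and an
individual contributes to a locus set only when fully typed there.

Statistics:

* **Hedrick's D′** — the multiallelic normalised LD coefficient: per allele
  pair D_ij = h_ij − p_i q_j, normalised by its sign-dependent maximum, then
  averaged with weights p_i q_j.
* **Cramér's Wn** — sqrt(χ² / (2N (min(k,l) − 1))), the [0,1]-normalised
  chi-square for deviations between observed and expected haplotype
  frequencies, computed over 2N estimated haplotypes.
* **Overall-LD test** — likelihood-ratio statistic between the EM haplotype
  solution and linkage equilibrium (products of allele frequencies), with a
  permutation null built by shuffling one locus's genotypes across
  individuals.
* **EM haplotype frequencies** — the classical genotype-phase EM for 2-3
  (or more) loci: ambiguous multi-locus genotypes are distributed over
  compatible haplotype pairs proportionally to current frequency products.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .nomenclature import AlleleNameError, parse_allele_name

__all__ = [
    "allele_frequencies",
    "HaplotypeEstimate",
    "em_haplotypes",
    "LDResult",
    "ld_pair",
    "ld_test",
]

GenotypeTable = Mapping[str, Mapping[str, tuple[str | None, str | None]]]


def _canonical(call: str | None, field_level: int) -> str | None:
    """Canonical allele string at >= field_level resolution, else None."""
    if call is None or call == "NA":
        return None
    try:
        name = parse_allele_name(call)
    except AlleleNameError:
        return None
    if name.resolution < field_level:
        return None
    k = min(field_level, name.resolution) if field_level else name.resolution
    fields = ":".join(str(int(f)) for f in name.fields[:k])
    return f"{name.locus}*{fields}"


def _complete_individuals(
    table: GenotypeTable, loci: Sequence[str], field_level: int
) -> list[tuple[tuple[str, str], ...]]:
    """Genotypes of individuals fully typed (at field_level) at all loci."""
    rows = []
    for sample in sorted(table):
        row = table[sample]
        geno = []
        for locus in loci:
            a1, a2 = row.get(locus, (None, None))
            c1, c2 = _canonical(a1, field_level), _canonical(a2, field_level)
            if c1 is None or c2 is None:
                geno = None
                break
            geno.append(tuple(sorted((c1, c2))))
        if geno is not None:
            rows.append(tuple(geno))
    return rows


def allele_frequencies(
    table: GenotypeTable, locus: str, field_level: int = 2
) -> dict[str, float]:
    """Allele frequencies by direct counting over retained call slots."""
    counts: dict[str, int] = {}
    for row in table.values():
        for slot in row.get(locus, (None, None)):
            c = _canonical(slot, field_level)
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no retained allele calls at {locus}")
    return {a: n / total for a, n in sorted(counts.items())}


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEstimate:
    loci: tuple[str, ...]
    frequencies: dict[tuple[str, ...], float]
    log_likelihood: float
    n_iterations: int
    n_individuals: int
    multimodal: bool = False
    allele_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)


def _expand_configs(
    geno: tuple[tuple[str, str], ...]
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All unordered haplotype pairs compatible with a multi-locus genotype."""
    het = [i for i, (a, b) in enumerate(geno) if a != b]
    configs = set()
    for bits in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = [], []
        flip = dict(zip(het, bits))
        for i, (a, b) in enumerate(geno):
            if i in flip and flip[i]:
                h1.append(b)
                h2.append(a)
            else:
                h1.append(a)
                h2.append(b)
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        configs.add(pair)
    return sorted(configs)


class _EMData:
    """Vectorised representation of the phase-ambiguity structure."""

    def __init__(self, genotypes: list[tuple[tuple[str, str], ...]]):
        if not genotypes:
            raise ValueError("no fully typed individuals")
        self.n = len(genotypes)
        hap_index: dict[tuple[str, ...], int] = {}
        I, A, B, C = [], [], [], []
        for i, geno in enumerate(genotypes):
            for h1, h2 in _expand_configs(geno):
                for h in (h1, h2):
                    if h not in hap_index:
                        hap_index[h] = len(hap_index)
                I.append(i)
                A.append(hap_index[h1])
                B.append(hap_index[h2])
                C.append(1.0 if h1 == h2 else 2.0)
        self.haplotypes = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
        self.I = np.asarray(I)
        self.A = np.asarray(A)
        self.B = np.asarray(B)
        self.C = np.asarray(C)
        self.k = len(self.haplotypes)

    def log_likelihood(self, f: np.ndarray) -> float:
        lik = np.zeros(self.n)
        np.add.at(lik, self.I, self.C * f[self.A] * f[self.B])
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(lik)))

    def em(
        self, f0: np.ndarray, tol: float, max_iter: int
    ) -> tuple[np.ndarray, float, int]:
        f = f0.copy()
        prev = -math.inf
        for it in range(1, max_iter + 1):
            w = self.C * f[self.A] * f[self.B]
            denom = np.zeros(self.n)
            np.add.at(denom, self.I, w)
            ll = float(np.sum(np.log(np.maximum(denom, 1e-300))))
            # EM guarantees monotone likelihood; numerical noise aside
            assert ll >= prev - 1e-9, "EM log-likelihood decreased"
            if ll - prev < tol:
                return f, ll, it
            prev = ll
            wn = w / denom[self.I]
            f_new = np.zeros(self.k)
            np.add.at(f_new, self.A, wn)
            np.add.at(f_new, self.B, wn)
            f = f_new / (2 * self.n)
        return f, prev, max_iter


def em_haplotypes(
    table: GenotypeTable,
    loci: Sequence[str],
    field_level: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 10,
    seed: int = 0,
) -> HaplotypeEstimate:
    """Maximum-likelihood haplotype frequencies for 2+ loci via EM.

    Restart 0 initialises from a uniform distribution over the observed
    phase configurations; further restarts draw Dirichlet starts. The best
    likelihood wins; ``multimodal`` flags runs where equally good restarts
    disagree in their frequencies (a known EM degeneracy, e.g. a single
    double heterozygote).
    """
    genotypes = _complete_individuals(table, loci, field_level)
    data = _EMData(genotypes)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, int] | None = None
    solutions: list[tuple[np.ndarray, float]] = []
    for r in range(max(1, n_restarts)):
        if r == 0:
            f0 = np.full(data.k, 1.0 / data.k)
        else:
            f0 = rng.dirichlet(np.ones(data.k))
        f, ll, its = data.em(f0, tol, max_iter)
        solutions.append((f, ll))
        if best is None or ll > best[1] + 1e-12:
            best = (f, ll, its)
    f, ll, its = best
    multimodal = any(
        abs(ll_r - ll) < 1e-6 and not np.allclose(f_r, f, atol=1e-4)
        for f_r, ll_r in solutions
    )
    freqs = {
        h: float(f[i]) for i, h in enumerate(data.haplotypes) if f[i] > 1e-12
    }
    afreq: dict[str, dict[str, float]] = {}
    for j, locus in enumerate(loci):
        margin: dict[str, float] = {}
        for h, p in zip(data.haplotypes, f):
            margin[h[j]] = margin.get(h[j], 0.0) + float(p)
        afreq[locus] = margin
    return HaplotypeEstimate(
        loci=tuple(loci),
        frequencies=freqs,
        log_likelihood=ll,
        n_iterations=its,
        n_individuals=data.n,
        multimodal=multimodal,
        allele_frequencies=afreq,
    )


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    loci: tuple[str, str]
    d_prime: float
    wn: float
    n_individuals: int
    p_perm: float | None = None
    n_perm: int = 0
    note: str = ""


def _ld_from_estimate(est: HaplotypeEstimate) -> tuple[float, float]:
    (locus_a, locus_b) = est.loci
    p = est.allele_frequencies[locus_a]
    q = est.allele_frequencies[locus_b]
    alleles_a = sorted(p)
    alleles_b = sorted(q)
    k, l = len(alleles_a), len(alleles_b)
    if k < 2 or l < 2:
        return float("nan"), float("nan")
    h = np.zeros((k, l))
    for (a, b), f in est.frequencies.items():
        h[alleles_a.index(a), alleles_b.index(b)] = f
    pv = np.array([p[a] for a in alleles_a])
    qv = np.array([q[b] for b in alleles_b])
    d = h - np.outer(pv, qv)
    d_prime = 0.0
    chi2 = 0.0
    two_n = 2 * est.n_individuals
    for i in range(k):
        for j in range(l):
            dij = d[i, j]
            if dij < 0:
                dmax = min(pv[i] * qv[j], (1 - pv[i]) * (1 - qv[j]))
            else:
                dmax = min(pv[i] * (1 - qv[j]), (1 - pv[i]) * qv[j])
            if dmax > 0:
                d_prime += pv[i] * qv[j] * abs(dij / dmax)
            exp = pv[i] * qv[j]
            if exp > 0:
                chi2 += two_n * dij * dij / exp
    wn = math.sqrt(chi2 / (two_n * (min(k, l) - 1)))
    return d_prime, min(wn, 1.0)


def ld_pair(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    estimate: HaplotypeEstimate | None = None,
    field_level: int = 2,
    em_seed: int = 0,
) -> LDResult:
    """Hedrick's D′ and Cramér's Wn between two loci (EM-based)."""
    if estimate is None:
        estimate = em_haplotypes(
            table, (locus_a, locus_b), field_level=field_level, seed=em_seed
        )
    d_prime, wn = _ld_from_estimate(estimate)
    note = "monomorphic locus" if math.isnan(d_prime) else ""
    return LDResult(
        loci=(locus_a, locus_b),
        d_prime=d_prime,
        wn=wn,
        n_individuals=estimate.n_individuals,
        note=note,
    )


def _lr_statistic(genotypes: list[tuple[tuple[str, str], ...]],
                  tol: float, max_iter: int) -> float:
    data = _EMData(genotypes)
    f, ll_em, _ = data.em(np.full(data.k, 1.0 / data.k), tol, max_iter)
    # independence null: haplotype freq = product of allele freqs counted
    # directly from the genotypes (their MLE under linkage equilibrium)
    margins: list[dict[str, float]] = [{} for _ in genotypes[0]]
    for geno in genotypes:
        for j, (a, b) in enumerate(geno):
            for allele in (a, b):
                margins[j][allele] = margins[j].get(allele, 0.0) + 1.0
    for m in margins:
        total = sum(m.values())
        for a in m:
            m[a] /= total
    f0 = np.array(
        [
            math.prod(margins[j][h[j]] for j in range(len(h)))
            for h in data.haplotypes
        ]
    )
    ll_0 = data.log_likelihood(f0)
    return 2.0 * (ll_em - ll_0)


def ld_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    field_level: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> LDResult:
    """Permutation likelihood-ratio test of overall LD between two loci.

    The observed statistic is 2(logL_EM − logL_independence); the null is
    built by shuffling locus-b genotypes across individuals, which preserves
    both single-locus genotype distributions while destroying association.
    p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genotypes = _complete_individuals(table, (locus_a, locus_b), field_level)
    if not genotypes:
        raise ValueError("no fully typed individuals")
    obs = _lr_statistic(genotypes, tol, max_iter)
    rng = np.random.default_rng(seed)
    a_part = [g[0] for g in genotypes]
    b_part = [g[1] for g in genotypes]
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(b_part))
        shuffled = [
            (a_part[i], b_part[perm[i]]) for i in range(len(a_part))
        ]
        if _lr_statistic(shuffled, tol, max_iter) >= obs - 1e-9:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    est = em_haplotypes(
        table, (locus_a, locus_b), field_level=field_level, seed=seed,
        n_restarts=3,
    )
    d_prime, wn = _ld_from_estimate(est)
    return LDResult(
        loci=(locus_a, locus_b),
        d_prime=d_prime,
        wn=wn,
        n_individuals=len(genotypes),
        p_perm=p,
        n_perm=n_perm,
        note="monomorphic locus" if math.isnan(d_prime) else "",
    )
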