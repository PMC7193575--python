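"""All-hits gapless local alignment against the padded allele panel.

The mapping contract: an L-base read is reported iff at least
``ceil(identity_threshold * L)`` of its bases match reference positions in a
single gapless placement, and *all* placements achieving the read's maximum
match count are kept (over both strands and every allele). With the default
threshold of 0.99 this reproduces a "1% mismatch" rule: reads shorter than
100 bases must match exactly, 100-199 base reads may carry one mismatch, and
so on. Keeping every equally-best placement is essential — most HLA reads are
expected to map ambiguously across alleles and often across paralogous loci.

Alignment is gapless by design: at >=99% identity on short reads at most one
indel could ever fit, exon panels are length-conserved after trimming, and a
gapless scorer can be checked exactly against a brute-force oracle. N bases
(read or reference) never count as matches.

Identical read sequences are collapsed before alignment and their
multiplicity retained: on ancient-DNA libraries these are PCR duplicates of
one original fragment, and duplicate counts later serve as evidence that a
variant is real rather than a polymerase/sequencing error.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .reference import N_CODE, ReferenceSet, encode
from .seqio import SeqRecord, revcomp

__all__ = ["Hit", "MappedRead", "min_score", "align_read", "map_all"]

DEFAULT_IDENTITY = 0.99
DEFAULT_MIN_READ_LEN = 25
_KMER = 13


def min_score(read_len: int, identity_threshold: float = DEFAULT_IDENTITY) -> int:
    """Minimum number of matching bases required to report an L-base read.

    ``ceil(threshold * L)`` with a guard against float noise, so that a
    threshold of 0.99 demands 99 matches of a 100-base read (one mismatch),
    not 100.
    """
    return int(math.ceil(round(identity_threshold * read_len, 9)))


@dataclass(frozen=True)
class Hit:
    """One equally-best gapless placement of a read on a panel allele."""

    allele: str
    locus: str
    ref_start: int  # padded coordinates, 0-based, of read base 0 (oriented)
    strand: str  # '+' or '-'
    score: int  # number of matching bases
    read_span: tuple[int, int]  # matched extent within the oriented read


@dataclass
class MappedRead:
    """A deduplicated read with its duplicate count and equally-best hits."""

    sequence: str
    dup_count: int
    hits: list[Hit]

    @property
    def loci(self) -> set[str]:
        return {h.locus for h in self.hits}

    @property
    def alleles_per_locus(self) -> dict[str, int]:
        counts: Counter[str] = Counter()
        seen = set()
        for h in self.hits:
            key = (h.locus, h.allele)
            if key not in seen:
                seen.add(key)
                counts[h.locus] += 1
        return dict(counts)

    def start_in(self, locus: str) -> int:
        """Start position within *locus*: minimum ref_start over its hits."""
        return min(h.ref_start for h in self.hits if h.locus == locus)

    def oriented_sequence(self, locus: str) -> str:
        """Read sequence re-oriented to the reference strand of *locus*."""
        h = min(
            (h for h in self.hits if h.locus == locus),
            key=lambda h: h.ref_start,
        )
        return self.sequence if h.strand == "+" else revcomp(self.sequence)


class KmerIndex:
    """Exact k-mer index over the panel for candidate-placement lookup.

    Seeding is provably lossless whenever a qualifying alignment must contain
    a mismatch-free stretch of at least k bases: with m allowed mismatches the
    longest clean stretch is >= (L - m) / (m + 1), which exceeds k = 13 for
    every read/threshold combination of practical interest. Where that bound
    fails (very short reads at permissive thresholds) the caller falls back to
    exhaustive scanning, preserving oracle equivalence.
    """

    def __init__(self, ref: ReferenceSet, k: int = _KMER):
        self.ref = ref
        self.k = k
        self.table: dict[str, list[tuple[str, int]]] = {}
        for allele in ref.alleles:
            seq = allele.padded_sequence
            name = str(allele.name)
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.table.setdefault(kmer, []).append((name, pos))

    def candidates(self, oriented: str, stride: int) -> set[tuple[str, int]]:
        """Candidate (allele, offset) placements from seed matches."""
        k = self.k
        L = len(oriented)
        out: set[tuple[str, int]] = set()
        positions = list(range(0, L - k + 1, stride))
        for p in positions:
            for name, pos in self.table.get(oriented[p : p + k], ()):  # noqa: E203
                offset = pos - p
                if 0 <= offset <= len(self.ref.allele(name).padded_sequence) - L:
                    out.add((name, offset))
        return out


def _score_placement(
    read_enc: np.ndarray, ref_enc: np.ndarray, offset: int
) -> tuple[int, tuple[int, int]]:
    window = ref_enc[offset : offset + len(read_enc)]  # noqa: E203
    match = (read_enc == window) & (window != N_CODE) & (read_enc != N_CODE)
    score = int(match.sum())
    if score == 0:
        return 0, (0, 0)
    idx = np.flatnonzero(match)
    return score, (int(idx[0]), int(idx[-1]) + 1)


def _exhaustive_candidates(ref: ReferenceSet, L: int) -> Iterable[tuple[str, int]]:
    for allele in ref.alleles:
        name = str(allele.name)
        for offset in range(len(allele.padded_sequence) - L + 1):
            yield name, offset


def align_read(
    read: str,
    ref: ReferenceSet,
    identity_threshold: float = DEFAULT_IDENTITY,
    index: KmerIndex | None = None,
    score_slack: int = 0,
) -> list[Hit]:
    """All equally-best gapless placements of *read*, or [] if none qualify.

    With ``score_slack > 0`` placements within that many matches of the best
    are retained too (still subject to the identity threshold).
    """
    read = read.upper()
    L = len(read)
    if L == 0:
        raise ValueError("empty read")
    need = min_score(L, identity_threshold)
    m_max = L - need
    # Longest guaranteed clean stretch under m_max mismatches.
    clean = (L - m_max) // (m_max + 1)
    use_index = index is not None and clean >= index.k
    if use_index:
        stride = max(1, clean - index.k + 1)

    placements: list[tuple[int, Hit]] = []
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        enc = encode(oriented)
        if use_index:
            cands = index.candidates(oriented, stride)
        else:
            cands = _exhaustive_candidates(ref, L)
        for name, offset in cands:
            ref_enc = ref.encoded(name)
            if offset < 0 or offset + L > len(ref_enc):
                continue
            score, span = _score_placement(enc, ref_enc, offset)
            if score >= need:
                hit = Hit(
                    allele=name,
                    locus=ref.allele(name).locus,
                    ref_start=offset,
                    strand=strand,
                    score=score,
                    read_span=span,
                )
                placements.append((score, hit))
    if not placements:
        return []
    best = max(s for s, _ in placements)
    keep = max(best - score_slack, need)
    hits = [h for s, h in placements if s >= keep]
    hits.sort(key=lambda h: (h.locus, h.allele, h.ref_start, h.strand))
    return hits


def map_all(
    reads: Iterable[str | SeqRecord],
    ref: ReferenceSet,
    identity_threshold: float = DEFAULT_IDENTITY,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    score_slack: int = 0,
    stats: dict | None = None,
    index: KmerIndex | None = None,
) -> list[MappedRead]:
    """Map a read stream: dedup exact sequences, align each once, keep the
    reads with at least one non-decoy hit.

    *stats*, when given a dict, is filled with a summary: total input reads,
    reads below the length floor, unmapped reads, reads discarded because all
    their placements were on decoy loci, and the number of distinct sequences.
    """
    counts: Counter[str] = Counter()
    n_total = n_short = 0
    for r in reads:
        seq = (r.sequence if isinstance(r, SeqRecord) else r).upper()
        n_total += 1
        if len(seq) < min_read_len:
            n_short += 1
            continue
        counts[seq] += 1

    if index is None:
        index = KmerIndex(ref)
    mapped: list[MappedRead] = []
    n_unmapped = n_decoy_only = 0
    for seq, dup in counts.items():
        hits = align_read(
            seq, ref, identity_threshold, index=index, score_slack=score_slack
        )
        if not hits:
            n_unmapped += dup
            continue
        if all(ref.is_decoy(h.locus) for h in hits):
            n_decoy_only += dup
            continue
        mapped.append(MappedRead(sequence=seq, dup_count=dup, hits=hits))
    if stats is not None:
        stats.update(
            total_reads=n_total,
            below_length_floor=n_short,
            unmapped=n_unmapped,
            decoy_only=n_decoy_only,
            distinct_sequences=len(counts),
            mapped_distinct=len(mapped),
        )
    return mapped


def build_mapped_reads(
    reads: Iterable[str],
    ref: ReferenceSet,
    identity_threshold: float = DEFAULT_IDENTITY,
    candidate_hits=None,
) -> list[MappedRead]:
    """Entry point used by the SAM importer: identical contract to map_all."""
    return map_all(reads, ref, identity_threshold=identity_threshold)
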