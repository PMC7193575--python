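"""Library- and locus-level enrichment quality metrics.

Definitions follow the capture-experiment bookkeeping conventions:

* endogenous % — reads mapping to the host genome over total reads (the
  genome alignment itself is external; counts are supplied).
* % on target — reads mapping to the HLA panel over total reads.
* fold enrichment — on-target reads after capture over on-target reads
  before; when the pre-capture count is zero the post-capture count itself
  is reported (the enrichment is unbounded but the yield is still
  informative).
* coverage — fraction of a locus's exon (non-N) sites touched by >= 1 read.
* weighted read depth — because most HLA reads map to several loci, each
  read's aligned length is down-weighted by the number of target loci it
  maps to, and reads with identical (start, end) placement — PCR/technical
  duplicates — are counted once per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mapping import MappedRead
from .reference import ReferenceSet

__all__ = [
    "coverage",
    "weighted_depth",
    "fold_enrichment",
    "endogenous_pct",
    "pct_on_target",
    "LibraryMetrics",
    "library_metrics",
]


def _locus_spans(read: MappedRead, locus: str) -> tuple[int, int]:
    """Aligned reference span of a read at a locus (its min-start hit)."""
    hit = min(
        (h for h in read.hits if h.locus == locus), key=lambda h: h.ref_start
    )
    s, e = hit.read_span
    return hit.ref_start + s, hit.ref_start + e


def coverage(locus: str, mapped: Iterable[MappedRead], ref: ReferenceSet) -> float:
    """Proportion of exon sites covered by at least one read."""
    mask = ref.non_n_mask(locus)
    hitmap = np.zeros(len(mask), dtype=bool)
    for read in mapped:
        if locus not in read.loci:
            continue
        s, e = _locus_spans(read, locus)
        hitmap[s:e] = True
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise ValueError(f"locus {locus} has no exon sites")
    return float((hitmap & mask).sum() / n_sites)


def weighted_depth(locus: str, mapped: Iterable[MappedRead], ref: ReferenceSet) -> float:
    """Multi-locus-weighted, position-deduplicated fold read depth."""
    n_sites = ref.n_exon_sites(locus)
    seen: set[tuple[int, int]] = set()
    total = 0.0
    for read in mapped:
        if locus not in read.loci:
            continue
        span = _locus_spans(read, locus)
        if span in seen:
            continue
        seen.add(span)
        n_target = sum(1 for l in read.loci if not ref.is_decoy(l))
        total += (span[1] - span[0]) / n_target
    return total / n_sites


def fold_enrichment(on_target_pre: int, on_target_post: int) -> float:
    """Post/pre on-target read ratio; the post count itself when pre is 0."""
    if on_target_pre < 0 or on_target_post < 0:
        raise ValueError("read counts must be non-negative")
    if on_target_pre == 0:
        return float(on_target_post)
    return on_target_post / on_target_pre


def endogenous_pct(mapped_to_genome: int, total: int) -> float:
    if total == 0:
        raise ValueError("total read count is zero")
    if mapped_to_genome > total:
        raise ValueError("mapped count exceeds total")
    return 100.0 * mapped_to_genome / total


def pct_on_target(on_target: int, total: int) -> float:
    if total == 0:
        raise ValueError("total read count is zero")
    return 100.0 * on_target / total


@dataclass
class LibraryMetrics:
    total_reads: int
    reads_on_reference: int
    reads_on_target: int
    endogenous_pct: float | None
    pct_on_target: float
    coverage_by_locus: dict[str, float]
    depth_by_locus: dict[str, float]

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(list(self.coverage_by_locus.values())))

    @property
    def mean_depth(self) -> float:
        return float(np.mean(list(self.depth_by_locus.values())))


def library_metrics(
    mapped: Sequence[MappedRead],
    ref: ReferenceSet,
    total_reads: int,
    reads_on_genome: int | None = None,
) -> LibraryMetrics:
    """Per-locus and averaged metrics for one library.

    ``reads_on_target`` counts read instances (duplicates included) with at
    least one non-decoy placement — the on-target count a capture report
    quotes. Averages run over the panel's target loci.
    """
    on_target = sum(m.dup_count for m in mapped)
    cov = {l: coverage(l, mapped, ref) for l in ref.target_loci}
    dep = {l: weighted_depth(l, mapped, ref) for l in ref.target_loci}
    return LibraryMetrics(
        total_reads=total_reads,
        reads_on_reference=on_target,
        reads_on_target=on_target,
        endogenous_pct=(
            endogenous_pct(reads_on_genome, total_reads)
            if reads_on_genome is not None
            else None
        ),
        pct_on_target=pct_on_target(on_target, total_reads),
        coverage_by_locus=cov,
        depth_by_locus=dep,
    )
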