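"""Group mapped reads by locus into ordered, annotated FASTA files.

Every read appears once per distinct target locus it maps to. Within a locus,
entries are ordered by how locus-specific the read is (number of target loci
it maps to, ascending — unique reads first), then by start position along the
locus, then by sequence as a deterministic tie-break. The emitted FASTA is
what an analyst would open in an alignment editor: reads stack along the
locus in reference orientation, with the duplicate count and the per-locus
allele counts carried in the header so that read-abundance evidence survives
the file format.

Header grammar (frozen here; any lossless encoding of these fields serves):

    >r0007|dup=3|loci=B:2;DRB1:1|start=137|strand=+
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .mapping import Hit, MappedRead
from .reference import ReferenceSet
from .seqio import revcomp

__all__ = ["LocusEntry", "LocusReadGroup", "sort_reads", "write_locus_fasta",
           "read_locus_fasta"]


@dataclass
class LocusEntry:
    """One read's appearance within a locus group."""

    read: MappedRead
    start: int  # min ref_start among this locus's hits (padded coords)
    n_loci: int  # distinct target loci the read maps to
    n_alleles: int  # alleles hit at this locus
    strand: str  # strand of the min-start hit at this locus

    @property
    def oriented(self) -> str:
        return self.read.sequence if self.strand == "+" else revcomp(self.read.sequence)


@dataclass
class LocusReadGroup:
    locus: str
    entries: list[LocusEntry]


def _sort_key(e: LocusEntry) -> tuple:
    return (e.n_loci, e.start, e.read.sequence)


def sort_reads(
    mapped: Iterable[MappedRead], ref: ReferenceSet
) -> dict[str, LocusReadGroup]:
    """Build per-locus ordered groups from mapped reads.

    A read mapping to k target loci contributes one entry to each of the k
    groups; reads whose placements are exclusively on decoy loci contribute
    nothing (the mapper normally drops them already).
    """
    groups: dict[str, list[LocusEntry]] = {}
    for read in mapped:
        target_loci = {l for l in read.loci if not ref.is_decoy(l)}
        per_locus = read.alleles_per_locus
        for locus in target_loci:
            locus_hits = [h for h in read.hits if h.locus == locus]
            first = min(locus_hits, key=lambda h: h.ref_start)
            groups.setdefault(locus, []).append(
                LocusEntry(
                    read=read,
                    start=first.ref_start,
                    n_loci=len(target_loci),
                    n_alleles=per_locus[locus],
                    strand=first.strand,
                )
            )
    return {
        locus: LocusReadGroup(locus, sorted(entries, key=_sort_key))
        for locus, entries in sorted(groups.items())
    }


# ---------------------------------------------------------------------------
# FASTA round trip
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^r(?P<idx>\d+)\|dup=(?P<dup>\d+)\|loci=(?P<loci>[^|]+)"
    r"\|start=(?P<start>\d+)\|strand=(?P<strand>[+-])$"
)


def write_locus_fasta(group: LocusReadGroup, path: str | Path) -> None:
    """Write one locus group as an annotated FASTA (reference orientation)."""
    with open(path, "w") as fh:
        for i, e in enumerate(group.entries):
            loci_field = ";".join(
                f"{locus}:{n}" for locus, n in sorted(e.read.alleles_per_locus.items())
            )
            fh.write(
                f">r{i:04d}|dup={e.read.dup_count}|loci={loci_field}"
                f"|start={e.start}|strand={e.strand}\n{e.oriented}\n"
            )


def read_locus_fasta(path: str | Path, locus: str) -> LocusReadGroup:
    """Parse a locus FASTA back into a (header-complete) LocusReadGroup.

    Hits are not reconstructed — only the fields the caller consumes: the
    oriented sequence, duplicate count, per-locus allele counts, start and
    strand. The synthetic MappedRead carries a single placeholder hit at this
    locus so that downstream grouping logic keeps working.
    """
    entries: list[LocusEntry] = []
    with open(path) as fh:
        header: str | None = None
        seq_lines: list[str] = []

        def flush() -> None:
            if header is None:
                return
            m = _HEADER_RE.match(header)
            if m is None:
                raise ValueError(f"unparseable locus FASTA header: >{header}")
            oriented = "".join(seq_lines).upper()
            loci_counts = {
                part.split(":")[0]: int(part.split(":")[1])
                for part in m.group("loci").split(";")
            }
            strand = m.group("strand")
            start = int(m.group("start"))
            sequence = oriented if strand == "+" else revcomp(oriented)
            hits = [
                Hit(
                    allele=f"{l}*{j:02d}",  # placeholder names, one per allele hit
                    locus=l,
                    ref_start=start if l == locus else 0,
                    strand=strand,
                    score=len(oriented),
                    read_span=(0, len(oriented)),
                )
                for l in sorted(loci_counts)
                for j in range(loci_counts[l])
            ]
            read = MappedRead(
                sequence=sequence, dup_count=int(m.group("dup")), hits=hits
            )
            entries.append(
                LocusEntry(
                    read=read,
                    start=start,
                    n_loci=len(loci_counts),
                    n_alleles=loci_counts.get(locus, 1),
                    strand=strand,
                )
            )

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                seq_lines = []
            elif line:
                seq_lines.append(line)
        flush()
    return LocusReadGroup(locus, entries)
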