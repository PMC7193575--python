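"""File formats: FASTA, FASTQ, SAM import, and genotype tables.

Thin wrappers around Biopython/pysam that normalise everything to the small
in-memory types the rest of the package uses. Sequences are uppercased on
input; coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

if TYPE_CHECKING:  # pragma: no cover
    from .mapping import MappedRead
    from .reference import ReferenceSet

__all__ = [
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "import_sam",
    "read_genotype_table",
    "write_genotype_table",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named sequence with free-form string annotations."""

    id: str
    sequence: str
    annotations: dict[str, str] = field(default_factory=dict)
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def read_fasta(path: str | Path | io.TextIOBase) -> list[SeqRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path | io.TextIOBase) -> None:
    bio = (_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    SeqIO.write(bio, path, "fasta")


def read_fastq(path: str | Path | io.TextIOBase) -> Iterator[SeqRecord]:
    """Stream FASTQ records (Sanger qualities)."""
    for rec in SeqIO.parse(path, "fastq"):
        yield SeqRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(records: Iterable[SeqRecord], path: str | Path | io.TextIOBase) -> None:
    def _bio() -> Iterator[_BioRecord]:
        for r in records:
            b = _BioRecord(Seq(r.sequence), id=r.id, description="")
            quals = r.qualities if r.qualities is not None else [40] * len(r.sequence)
            b.letter_annotations["phred_quality"] = quals
            yield b

    SeqIO.write(_bio(), path, "fastq")


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

def import_sam(
    path: str | Path,
    ref: "ReferenceSet",
    identity_threshold: float = 0.99,
    min_read_len: int = 25,
) -> "list[MappedRead]":
    """Import externally produced alignments and rebuild ``MappedRead``s.

    Each alignment line contributes a candidate hit; scores are recomputed
    against *ref* with the package's own gapless scoring so that imported and
    internally mapped reads obey the same contract (all equally-best hits at
    >= ceil(threshold x L) matching bases). Reads are collapsed by exact
    sequence identity with the number of distinct input reads per sequence
    kept as the duplicate count.
    """
    import pysam

    from .mapping import build_mapped_reads

    # Recover one as-sequenced read per query name; alignments themselves are
    # re-derived internally so that imported and internally mapped reads obey
    # the same equally-best contract regardless of what the external mapper
    # chose to report.
    seqs: dict[str, str] = {}
    known_refs = {str(a.name) for a in ref.alleles}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if aln.reference_name is not None and aln.reference_name not in known_refs:
                raise ValueError(
                    f"SAM reference {aln.reference_name!r} not in the active panel"
                )
            seq = aln.query_sequence.upper()
            # SAM stores the reference-strand sequence; flip reverse-strand
            # alignments back to the read as sequenced.
            read_seq = revcomp(seq) if aln.is_reverse else seq
            prev = seqs.setdefault(aln.query_name, read_seq)
            if prev not in (read_seq, revcomp(read_seq)):
                raise ValueError(
                    f"read {aln.query_name!r} has inconsistent sequences in SAM"
                )

    reads = [s for s in seqs.values() if len(s) >= min_read_len]
    return build_mapped_reads(reads, ref, identity_threshold=identity_threshold)


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

def write_genotype_table(
    table: "dict[str, dict[str, tuple[str | None, str | None]]]",
    path: str | Path | io.TextIOBase,
    loci: list[str] | None = None,
) -> None:
    """Write a samples x loci genotype table as TSV.

    Columns: ``sample_id`` then ``<locus>_1``, ``<locus>_2`` per locus; the
    literal ``NA`` marks a slot where no call was possible.
    """
    if loci is None:
        loci = sorted({l for row in table.values() for l in row})
    rows = []
    for sample, row in table.items():
        out: dict[str, str] = {"sample_id": sample}
        for locus in loci:
            a1, a2 = row.get(locus, (None, None))
            out[f"{locus}_1"] = a1 if a1 is not None else "NA"
            out[f"{locus}_2"] = a2 if a2 is not None else "NA"
        rows.append(out)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(
    path: str | Path | io.TextIOBase,
) -> "dict[str, dict[str, tuple[str | None, str | None]]]":
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("genotype table needs a sample_id column")
    loci = []
    for col in df.columns:
        if col.endswith("_1"):
            locus = col[:-2]
            if f"{locus}_2" not in df.columns:
                raise ValueError(f"locus {locus!r} lacks a second allele column")
            loci.append(locus)
    table: dict[str, dict[str, tuple[str | None, str | None]]] = {}
    for _, row in df.iterrows():
        entry: dict[str, tuple[str | None, str | None]] = {}
        for locus in loci:
            a1 = row[f"{locus}_1"] or "NA"
            a2 = row[f"{locus}_2"] or "NA"
            entry[locus] = (None if a1 == "NA" else a1, None if a2 == "NA" else a2)
        table[str(row["sample_id"])] = entry
    return table
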