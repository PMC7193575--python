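"""Mapping-reference construction for targeted HLA genotyping.

The mapping panel holds, per locus, the exon sequences that encode the
peptide-binding groove (exons 2+3 for class I genes, exon 2 for class II).
Building it from per-locus alignments involves three steps:

1. :func:`trim_alignment` — drop alignment columns created by rare
   non-functional alleles and any columns outside the exon bounds, leaving
   gap-free, equal-length exon sequences.
2. :func:`collapse_g_groups` — merge alleles whose exon sequence is identical
   (the G-group convention); the lowest-numbered member names the record.
3. :func:`build_reference` — pad each record with N runs: ``pad_flank`` Ns on
   both ends and, for class I loci, ``pad_spacer`` Ns between exon 2 and 3 in
   place of the (mostly unknown) intron, so that reads crossing an
   exon boundary still have somewhere to sit.

Decoy loci (paralogous non-classical genes) are carried in the panel purely
to absorb reads that would otherwise mis-map onto a classical locus; the
sorter discards reads whose only placements are decoys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nomenclature import AlleleName, parse_allele_name
from .seqio import SeqRecord, read_fasta

__all__ = [
    "LocusConfig",
    "ReferenceAllele",
    "ReferenceSet",
    "collapse_g_groups",
    "trim_alignment",
    "build_reference",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T,N} as uint8 codes (N never matches)."""
    try:
        return np.fromiter((_BASE_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unexpected base {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class LocusConfig:
    """Descriptor of one locus in the panel."""

    name: str
    hla_class: int  # 1 (exons 2+3, internal spacer) or 2 (exon 2 only)
    decoy: bool = False


@dataclass
class ReferenceAllele:
    """One padded panel record: a G-group representative and its members."""

    name: AlleleName
    locus: str
    padded_sequence: str
    exon_spans: list[tuple[int, int]]
    members: list[AlleleName]

    @property
    def exon_sequence(self) -> str:
        return "".join(
            self.padded_sequence[s:e] for s, e in self.exon_spans
        )


class ReferenceSet:
    """The combined per-locus allele panel used for mapping and calling."""

    def __init__(
        self,
        alleles: list[ReferenceAllele],
        loci: list[LocusConfig],
        pad_flank: int = 100,
        pad_spacer: int = 20,
    ):
        names = [str(a.name) for a in alleles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate allele names in reference")
        self.alleles = list(alleles)
        self.loci = {l.name: l for l in loci}
        self.pad_flank = pad_flank
        self.pad_spacer = pad_spacer
        self._by_locus: dict[str, list[ReferenceAllele]] = {}
        for a in self.alleles:
            if a.locus not in self.loci:
                raise ValueError(f"allele {a.name} references unknown locus {a.locus}")
            self._by_locus.setdefault(a.locus, []).append(a)
        for cfg in loci:
            if not cfg.decoy and not self._by_locus.get(cfg.name):
                raise ValueError(f"target locus {cfg.name} has no alleles")
        self._by_name = {str(a.name): a for a in self.alleles}
        self._encoded: dict[str, np.ndarray] = {}

    # -- lookups ------------------------------------------------------------

    def alleles_at(self, locus: str) -> list[ReferenceAllele]:
        return self._by_locus.get(locus, [])

    def allele(self, name: str) -> ReferenceAllele:
        return self._by_name[name]

    @property
    def target_loci(self) -> list[str]:
        return [n for n, c in self.loci.items() if not c.decoy]

    def is_decoy(self, locus: str) -> bool:
        return self.loci[locus].decoy

    def encoded(self, name: str) -> np.ndarray:
        arr = self._encoded.get(name)
        if arr is None:
            arr = encode(self._by_name[name].padded_sequence)
            self._encoded[name] = arr
        return arr

    # -- per-locus geometry (all alleles of a locus share it) ---------------

    def locus_length(self, locus: str) -> int:
        return len(self.alleles_at(locus)[0].padded_sequence)

    def exon_spans(self, locus: str) -> list[tuple[int, int]]:
        return self.alleles_at(locus)[0].exon_spans

    def non_n_mask(self, locus: str) -> np.ndarray:
        """Boolean mask over padded coordinates: True at exon (non-N) sites."""
        mask = np.zeros(self.locus_length(locus), dtype=bool)
        for s, e in self.exon_spans(locus):
            mask[s:e] = True
        return mask

    def n_exon_sites(self, locus: str) -> int:
        return sum(e - s for s, e in self.exon_spans(locus))

    def exon_to_padded(self, locus: str, pos: int) -> int:
        """Map an exon-concatenation coordinate to padded locus coordinates."""
        off = pos
        for s, e in self.exon_spans(locus):
            if off < e - s:
                return s + off
            off -= e - s
        raise IndexError(f"exon position {pos} out of range for {locus}")


# ---------------------------------------------------------------------------
# Reference-building operations
# ---------------------------------------------------------------------------

def collapse_g_groups(
    alleles: list[tuple[AlleleName, str]],
) -> list[ReferenceAllele]:
    """Merge alleles with identical exon sequence into one record.

    The representative is the lowest-numbered member (numeric field order,
    matching the G-group convention of naming groups by their first allele)
    and carries the G flag whenever more than one allele collapsed into it.
    Input sequences must already be gap-free and, per locus, equal length.
    """
    seen: set[str] = set()
    for name, _ in alleles:
        key = name.format()
        if key in seen:
            raise ValueError(f"duplicate input allele name {name}")
        seen.add(key)

    by_seq: dict[tuple[str, str], list[AlleleName]] = {}
    order: list[tuple[str, str]] = []
    for name, seq in alleles:
        if set(seq) - set("ACGT"):
            raise ValueError(f"allele {name} has non-ACGT characters")
        key = (name.locus, seq)
        if key not in by_seq:
            order.append(key)
        by_seq.setdefault(key, []).append(name)

    records = []
    for locus, seq in order:
        members = sorted(by_seq[(locus, seq)])
        rep = members[0]
        g = len(members) > 1
        records.append(
            ReferenceAllele(
                name=AlleleName(rep.locus, rep.fields, g_group=g or rep.g_group),
                locus=locus,
                padded_sequence=seq,  # padding applied by build_reference
                exon_spans=[(0, len(seq))],
                members=members,
            )
        )
    return records


def trim_alignment(
    msa: list[str],
    exon_bounds: tuple[int, int] | None = None,
    gap_col_fraction: float = 0.95,
    ids: list[str] | None = None,
) -> tuple[list[str], list[int]]:
    """Strip rare-insertion columns and out-of-exon overhangs from an MSA.

    A column is removed when it is gapped in at least *gap_col_fraction* of
    rows (an insertion private to rare alleles) or lies outside
    *exon_bounds* (alignment coordinates, 0-based half-open). Rows that still
    contain gaps afterwards (rare deletion alleles) are dropped with a
    warning. Returns the ungapped sequences and the indices of kept rows.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows differ in length")
    arr = np.array([list(row.upper()) for row in msa])
    gap_frac = (arr == "-").mean(axis=0)
    keep_cols = gap_frac < gap_col_fraction
    if exon_bounds is not None:
        s, e = exon_bounds
        in_exon = np.zeros(width, dtype=bool)
        in_exon[s:e] = True
        keep_cols &= in_exon
    trimmed = arr[:, keep_cols]
    out: list[str] = []
    kept_rows: list[int] = []
    for i, row in enumerate(trimmed):
        seq = "".join(row)
        if "-" in seq:
            label = ids[i] if ids is not None else f"row {i}"
            warnings.warn(
                f"{label}: residual gaps after column trimming; row dropped",
                stacklevel=2,
            )
            continue
        out.append(seq)
        kept_rows.append(i)
    if not out:
        raise ValueError("no rows left after trimming")
    return out, kept_rows


def _pad(record: ReferenceAllele, cfg: LocusConfig, exon_lengths: list[int],
         pad_flank: int, pad_spacer: int) -> ReferenceAllele:
    flank = "N" * pad_flank
    seq = record.padded_sequence  # still the bare exon concatenation here
    if cfg.hla_class == 1:
        if len(exon_lengths) != 2:
            raise ValueError(
                f"class I locus {cfg.name} needs two exon lengths, got {exon_lengths}"
            )
        e2, e3 = exon_lengths
        spacer = "N" * pad_spacer
        padded = flank + seq[:e2] + spacer + seq[e2:] + flank
        spans = [
            (pad_flank, pad_flank + e2),
            (pad_flank + e2 + pad_spacer, pad_flank + e2 + pad_spacer + e3),
        ]
    else:
        padded = flank + seq + flank
        spans = [(pad_flank, pad_flank + len(seq))]
    return ReferenceAllele(
        name=record.name,
        locus=record.locus,
        padded_sequence=padded,
        exon_spans=spans,
        members=record.members,
    )


def build_reference(
    per_locus: dict[str, list[tuple[AlleleName, str]]],
    loci: list[LocusConfig],
    exon_lengths: dict[str, list[int]],
    pad_flank: int = 100,
    pad_spacer: int = 20,
) -> ReferenceSet:
    """Assemble the padded, G-group-collapsed panel.

    Parameters
    ----------
    per_locus:
        Gap-free exon concatenations per locus (output of
        :func:`trim_alignment` plus name parsing).
    exon_lengths:
        Exon lengths per locus; two entries for class I (exons 2 and 3), one
        for class II. Their sum must equal the sequence length at the locus.
    """
    cfg_by_name = {c.name: c for c in loci}
    records: list[ReferenceAllele] = []
    for locus, alleles in per_locus.items():
        if locus not in cfg_by_name:
            raise ValueError(f"no locus config for {locus}")
        cfg = cfg_by_name[locus]
        lengths = exon_lengths[locus]
        total = sum(lengths)
        for name, seq in alleles:
            if len(seq) != total:
                raise ValueError(
                    f"{name}: sequence length {len(seq)} != exon total {total}"
                )
        collapsed = collapse_g_groups(alleles)
        if not collapsed:
            raise ValueError(f"locus {locus} empty after collapsing")
        records.extend(
            _pad(rec, cfg, lengths, pad_flank, pad_spacer) for rec in collapsed
        )
    return ReferenceSet(records, loci, pad_flank=pad_flank, pad_spacer=pad_spacer)


# ---------------------------------------------------------------------------
# On-disk form: combined FASTA + sidecar TSV
# ---------------------------------------------------------------------------

def write_reference(ref: ReferenceSet, fasta_path: str | Path, tsv_path: str | Path) -> None:
    from .seqio import write_fasta

    write_fasta(
        [SeqRecord(id=str(a.name), sequence=a.padded_sequence) for a in ref.alleles],
        fasta_path,
    )
    import pandas as pd

    rows = []
    for a in ref.alleles:
        cfg = ref.loci[a.locus]
        rows.append(
            {
                "name": str(a.name),
                "locus": a.locus,
                "class": cfg.hla_class,
                "decoy": int(cfg.decoy),
                "exon_spans": ";".join(f"{s}-{e}" for s, e in a.exon_spans),
                "members": ";".join(str(m) for m in a.members),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_reference(fasta_path: str | Path, tsv_path: str | Path,
                   pad_flank: int = 100, pad_spacer: int = 20) -> ReferenceSet:
    import pandas as pd

    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    alleles = []
    loci: dict[str, LocusConfig] = {}
    for _, row in df.iterrows():
        name = parse_allele_name(row["name"])
        spans = [
            tuple(int(x) for x in part.split("-"))
            for part in row["exon_spans"].split(";")
        ]
        alleles.append(
            ReferenceAllele(
                name=name,
                locus=row["locus"],
                padded_sequence=seqs[row["name"]],
                exon_spans=[(s, e) for s, e in spans],
                members=[parse_allele_name(m) for m in row["members"].split(";")],
            )
        )
        loci.setdefault(
            row["locus"],
            LocusConfig(row["locus"], int(row["class"]), bool(int(row["decoy"]))),
        )
    return ReferenceSet(alleles, list(loci.values()), pad_flank, pad_spacer)
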