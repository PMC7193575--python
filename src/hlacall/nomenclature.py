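"""HLA allele nomenclature.

Alleles of an HLA gene are named by the locus followed by a hierarchical,
colon-separated numbering: the 1st field groups related alleles ("allele
group" / lineage), the 2nd field separates alleles with distinct protein
sequences, and the 3rd field distinguishes synonymous exonic variants.
A trailing ``G`` marks a G-group: the set of alleles sharing an identical
nucleotide sequence across the exons encoding the peptide-binding groove.

Fields are stored as strings so that leading zeros survive a round trip
(``"01"`` prints as ``01``), but names compare *numerically* field by field,
so ``A*01:01`` equals ``A*1:1``. The ``HLA-`` prefix is optional on input and
emitted on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

__all__ = ["AlleleName", "AlleleNameError", "parse_allele_name", "round_to_field"]


class AlleleNameError(ValueError):
    """Raised when an allele name cannot be parsed or manipulated."""


_NAME_RE = re.compile(
    r"""^(?:[Hh][Ll][Aa]-)?
        (?P<locus>[A-Za-z][A-Za-z0-9]*)
        \*
        (?P<fields>[0-9]+(?::[0-9]+){0,3})
        (?P<g>G)?$""",
    re.VERBOSE,
)


@total_ordering
@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele identifier at 1-4 fields of resolution.

    Parameters
    ----------
    locus:
        Gene name without the ``HLA-`` prefix, e.g. ``"B"`` or ``"DRB1"``.
    fields:
        Tuple of 1-4 numeric tokens kept as zero-padded strings.
    g_group:
        True when the name designates a G-group (trailing ``G``).
    """

    locus: str
    fields: tuple[str, ...]
    g_group: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleNameError("allele name needs at least one field")
        if not all(f.isdigit() for f in self.fields):
            raise AlleleNameError(f"non-numeric field in {self.fields!r}")

    # -- formatting ---------------------------------------------------------

    def format(self, prefix: bool = True) -> str:
        g = "G" if self.g_group else ""
        head = f"HLA-{self.locus}" if prefix else self.locus
        return f"{head}*{':'.join(self.fields)}{g}"

    def __str__(self) -> str:  # short form, as used in result tables
        return self.format(prefix=False)

    # -- comparison (numeric, padding-insensitive) --------------------------

    @property
    def numeric_fields(self) -> tuple[int, ...]:
        return tuple(int(f) for f in self.fields)

    def _key(self) -> tuple:
        return (self.locus, self.numeric_fields, self.g_group)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self._key() == other._key()

    def __lt__(self, other: "AlleleName") -> bool:
        return self._key() < other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    # -- resolution ---------------------------------------------------------

    @property
    def resolution(self) -> int:
        """Number of fields carried by this name (1-4)."""
        return len(self.fields)

    def first_field_equivalent(self, other: "AlleleName") -> bool:
        """True iff the two names share locus and allele group (1st field)."""
        return self.locus == other.locus and int(self.fields[0]) == int(other.fields[0])


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``[HLA-]LOCUS*F1[:F2[:F3[:F4]]][G]`` into an :class:`AlleleName`.

    >>> parse_allele_name("DRB1*15:01")
    AlleleName(locus='DRB1', fields=('15', '01'), g_group=False)
    """
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise AlleleNameError(f"malformed allele name: {text!r}")
    return AlleleName(
        locus=m.group("locus").upper(),
        fields=tuple(m.group("fields").split(":")),
        g_group=m.group("g") is not None,
    )


def round_to_field(name: AlleleName, k: int) -> AlleleName:
    """Truncate *name* to its first *k* fields.

    Rounding to a coarser resolution drops the G-group marker (a G-group is
    defined at 3rd-field nucleotide identity, which a truncated name no longer
    asserts) unless the name is returned unchanged. Idempotent.
    """
    if k < 1:
        raise AlleleNameError(f"field level must be >= 1, got {k}")
    if k > len(name.fields):
        raise AlleleNameError(
            f"{name} carries {len(name.fields)} field(s); cannot round to {k}"
        )
    if k == len(name.fields):
        return name
    return AlleleName(locus=name.locus, fields=name.fields[:k], g_group=False)
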