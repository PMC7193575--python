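"""Evaluation measures for genotype call sets.

Three rates summarise a call table, each with explicit NA conventions:

* **success rate** — called alleles over assayed alleles (two per locus and
  sample). A slot counts as called at field level k only when its name
  carries at least k fields; ambiguous calls are NA and stay in the
  denominator only.
* **accuracy rate** — correct over correct + incorrect, with NA slots (and
  slots below the requested resolution) excluded from both numerator and
  denominator. Requires truth for every called slot.
* **agreement** — identical calls between two independent call sets over
  the slots called in both.

Genotypes are unordered: the two call slots are compared with the two truth
slots under the pairing that maximises matches (two pairings, exhaustive).
"""

from __future__ import annotations

from typing import Mapping

from .nomenclature import AlleleNameError, parse_allele_name

__all__ = ["success_rate", "accuracy_rate", "agreement"]

# A genotype table: sample -> locus -> (allele_1, allele_2), strings or None.
GenotypeTable = Mapping[str, Mapping[str, tuple[str | None, str | None]]]


def _key(call: str | None, level: int) -> tuple | None:
    """Comparison key of a call at a field level; None when NA at that level."""
    if call is None or call == "NA":
        return None
    try:
        name = parse_allele_name(call)
    except AlleleNameError as exc:
        raise ValueError(f"unparseable allele call {call!r}") from exc
    if name.resolution < level:
        return None
    return (name.locus, name.numeric_fields[:level])


def _pair_scores(
    a: tuple[tuple | None, tuple | None], b: tuple[tuple | None, tuple | None]
) -> tuple[int, int]:
    """(matches, comparisons) under the better of the two slot pairings.

    A comparison happens only where both sides of a pair are non-NA; the
    pairing maximising matches (ties: more comparisons) wins.
    """
    best = (-1, -1)
    for order in ((0, 1), (1, 0)):
        matches = comparisons = 0
        for i, j in enumerate(order):
            if a[i] is None or b[j] is None:
                continue
            comparisons += 1
            if a[i] == b[j]:
                matches += 1
        if (matches, comparisons) > best:
            best = (matches, comparisons)
    return best


def success_rate(calls: GenotypeTable, field_level: int = 1) -> float:
    """Percent of assayed alleles called at >= *field_level* resolution."""
    n_slots = n_called = 0
    for row in calls.values():
        for pair in row.values():
            for slot in pair:
                n_slots += 1
                if _key(slot, field_level) is not None:
                    n_called += 1
    if n_slots == 0:
        raise ValueError("empty genotype table")
    return 100.0 * n_called / n_slots


def accuracy_rate(
    calls: GenotypeTable, truth: GenotypeTable, field_level: int = 1
) -> float:
    """Percent of called alleles matching truth at *field_level*.

    NA and below-resolution calls are excluded entirely; truth slots that
    are themselves NA at the level (e.g. unknown second allele) are likewise
    not compared.
    """
    matches = comparisons = 0
    for sample, row in calls.items():
        if sample not in truth:
            raise ValueError(f"truth table lacks sample {sample!r}")
        for locus, pair in row.items():
            if any(_key(s, 1) is not None for s in pair):
                if locus not in truth[sample]:
                    raise ValueError(
                        f"truth table lacks locus {locus!r} for {sample!r}"
                    )
            t_pair = truth[sample].get(locus, (None, None))
            a = tuple(_key(s, field_level) for s in pair)
            b = tuple(_key(s, field_level) for s in t_pair)
            m, c = _pair_scores(a, b)
            matches += m
            comparisons += c
    if comparisons == 0:
        return float("nan")
    return 100.0 * matches / comparisons


def agreement(
    calls_a: GenotypeTable, calls_b: GenotypeTable, field_level: int = 1
) -> float:
    """Percent of identically typed alleles between two call sets.

    Slots NA in either set are excluded. Symmetric in its arguments; raises
    when the sample sets differ, returns NaN when nothing is comparable.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("the two call sets cover different samples")
    matches = comparisons = 0
    for sample, row in calls_a.items():
        loci = set(row) | set(calls_b[sample])
        for locus in loci:
            a = tuple(_key(s, field_level) for s in row.get(locus, (None, None)))
            b = tuple(
                _key(s, field_level)
                for s in calls_b[sample].get(locus, (None, None))
            )
            m, c = _pair_scores(a, b)
            matches += m
            comparisons += c
    if comparisons == 0:
        return float("nan")
    return 100.0 * matches / comparisons
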