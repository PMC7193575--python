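"""A synthetic two-locus HLA world for end-to-end validation.

Real HLA panels have a layered polymorphism structure: alleles fall into
1st-field groups ("lineages") separated by many sites, alleles within a
group differ at a handful of sites, and some alleles are distinguished only
outside the peptide-binding exons (G-groups). The toy world reproduces that
structure at desk scale so the whole pipeline — mapping, sorting, calling,
novel-allele detection, evaluation — can be exercised against known truth:

* Two target loci: ``B`` (class I, exons 2+3 of 270 and 276 bp) and
  ``DRB1`` (class II, exon 2 of 270 bp), five 1st-field groups each, four
  alleles per group, ~20 panel records per locus.
* Each group carries eight private "group sites" (variant base in every
  member); within-group alleles differ at one or two "allele sites". One
  allele pair per locus is exon-identical and collapses into a G-group.
* Seven haplotypes combined into six heterozygous diploid genotypes; three
  "de-novo" point mutations are injected into two of the haplotypes (one at
  each locus of the first, one at the second's DRB1).

Novel-mutation placement mirrors a property of the real panel that matters
under a ~1% mismatch threshold (exact matching for sub-100 bp reads): a read
carrying a novel base can only map if some other panel allele carries that
base at that position. Each injected mutation therefore sits at the private
variant site of a dedicated *donor allele* from a different allele group,
inside a window that is otherwise invariant between the source and donor
groups. Reads spanning the mutation map perfectly onto the donor allele,
while the assembled consensus — source-group pattern plus the novel base —
matches no panel allele at all, which is exactly the signature the caller's
novel-allele detector looks for. The donor differs from the consensus at 16
well-spread sites, so it is excluded even at low coverage.

Everything here is deterministic: the ancestral sequences come from a fixed
internal seed, and all site positions are fixed constants chosen to respect
the window constraints (asserted at build time).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .calling import CwdList
from .nomenclature import AlleleName, parse_allele_name
from .reference import LocusConfig, ReferenceSet, build_reference
from .simulate import Haplotype, build_haplotype

__all__ = ["ToyWorld", "toy_world", "toy_panel_input"]

_PANEL_SEED = 20200430  # fixes the ancestral sequences; not a knob

# transition-style variant base at a polymorphic site
_VARIANT = {"A": "G", "G": "A", "C": "T", "T": "C"}

# ---------------------------------------------------------------------------
# Site layout (exon-concatenation coordinates)
# ---------------------------------------------------------------------------
# Within-group "allele" site pairs sit within one read length of each other
# (<= 74 bp) so that heterozygous same-group genotypes can be phased by
# physically overlapping reads rather than by guesswork.
#
# B: exons 270 + 276 (junction at 270; the padded reference carries a 20 N
# spacer there, so no read may span it). The novel site NOVEL_B lies deep in
# exon 3; the source group (07) and both donor groups (44, 08) have no sites
# within +-80 of it.
_B_GROUPS = ["07", "08", "15", "40", "44"]
_B_SITES = {
    "07": {"group": [15, 55, 95, 135, 175, 215, 255, 295], "allele": [35, 85]},
    "44": {"group": [20, 60, 100, 140, 180, 220, 260, 300], "allele": [40, 90]},
    "08": {"group": [25, 75, 125, 225, 490, 505, 515, 525], "allele": [45, 105]},
    "15": {"group": [30, 80, 130, 230, 330, 380, 430, 495], "allele": [50, 115]},
    "40": {"group": [10, 70, 110, 210, 310, 360, 410, 500], "allele": [65, 120]},
}
NOVEL_B = 400  # donors: B*44:05, B*08:05
_B_WINDOW = (320, 480)  # free of group-07, group-44 and group-08 sites
_B_SOURCE_DONORS = ("07", ("44", "08"))

# DRB1: single 270 bp exon, two novel sites. Window A around NOVEL_DRB1_A
# must be invariant between the source group 01 and site A's donor alleles;
# window B around NOVEL_DRB1_B likewise for source group 15 and site B's
# donors. Each novel site has two free-standing donor alleles from distinct
# (otherwise unused) allele groups, with interior private sites of their
# own: a sparse consensus carrying only the novel base therefore matches
# several allele groups at once (→ ambiguous, NA) instead of implicating a
# single unfalsifiable rare allele, mirroring the density of the real
# panel.
_DRB1_GROUPS = ["01", "03", "04", "07", "15"]
_DRB1_SITES = {
    "01": {"group": [172, 184, 196, 208, 220, 232, 244, 256], "allele": [178, 202]},
    "03": {"group": [175, 187, 199, 211, 223, 235, 247, 259], "allele": [181, 205]},
    "04": {"group": [176, 192, 204, 216, 228, 240, 252, 264], "allele": [188, 224]},
    "07": {"group": [15, 27, 39, 51, 63, 75, 87, 99], "allele": [21, 45]},
    "15": {"group": [12, 24, 36, 48, 60, 72, 84, 96], "allele": [18, 42]},
}
NOVEL_DRB1_A = 90  # source group 01
NOVEL_DRB1_B = 180  # source group 15
_DRB1_WINDOW_A = (10, 170)
_DRB1_WINDOW_B = (100, 260)

# donor name -> (private sites, novel site carried)
_DRB1_DONORS = {
    "09:01": ([173, 189, 197, 213, 221, 237, 245, 261], NOVEL_DRB1_A),
    "10:01": ([177, 193, 209, 225, 241, 257, 263, 266], NOVEL_DRB1_A),
    "08:01": ([30, 33, 54, 57, 66, 78, 81, 93], NOVEL_DRB1_B),
    "11:01": ([0, 3, 6, 9, 59, 69, 82, 94], NOVEL_DRB1_B),
}
_B_DONORS = {
    "44:05": (_B_SITES["44"]["group"], NOVEL_B),
    "08:05": (_B_SITES["08"]["group"], NOVEL_B),
}

_EXON_LENGTHS = {"B": [270, 276], "DRB1": [270]}


def _check_layout() -> None:
    def outside(sites: list[int], lo: int, hi: int) -> bool:
        return all(not (lo <= s <= hi) for s in sites)

    def check_window(layout, donors, window, source, novel_site):
        for kind in ("group", "allele"):
            assert outside(layout[source][kind], *window), (source, kind)
        for name, (sites, site) in donors.items():
            if site == novel_site:
                assert outside(sites, *window), (name, window)

    check_window(_B_SITES, _B_DONORS, _B_WINDOW, "07", NOVEL_B)
    check_window(_DRB1_SITES, _DRB1_DONORS, _DRB1_WINDOW_A, "01", NOVEL_DRB1_A)
    check_window(_DRB1_SITES, _DRB1_DONORS, _DRB1_WINDOW_B, "15", NOVEL_DRB1_B)
    for sites, donors, novel, n in (
        (_B_SITES, _B_DONORS, [NOVEL_B], sum(_EXON_LENGTHS["B"])),
        (_DRB1_SITES, _DRB1_DONORS, [NOVEL_DRB1_A, NOVEL_DRB1_B], 270),
    ):
        all_sites = [s for d in sites.values() for v in d.values() for s in v]
        donor_own = [
            s for name, (ds, _) in donors.items() for s in ds
            if s not in all_sites
        ]
        combined = all_sites + donor_own
        assert len(combined) == len(set(combined)), "site collision"
        assert all(0 <= s < n for s in combined)
        for d in sites.values():
            a1, a2 = d["allele"]
            assert abs(a2 - a1) <= 74, "allele sites not linkable by one read"
        for site in novel:
            assert site not in combined, "novel site collides with a variant site"


_check_layout()


def _ancestral(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _apply_sites(base: str, sites: list[int]) -> str:
    seq = list(base)
    for s in sites:
        seq[s] = _VARIANT[seq[s]]
    return "".join(seq)


def _locus_alleles(
    locus: str,
    anc: str,
    groups: list[str],
    layout: dict[str, dict[str, list[int]]],
    g_pair_group: str,
    donors: dict[str, tuple[list[int], int]],
) -> list[tuple[AlleleName, str]]:
    """Panel input for one locus: 4 alleles per group, one exon-identical
    3rd-field pair (the future G-group), plus the novel-site donor alleles
    (rare alleles carrying their own private sites and the novel base)."""
    out: list[tuple[AlleleName, str]] = []
    for grp in groups:
        gsites = layout[grp]["group"]
        a1, a2 = layout[grp]["allele"]
        base = _apply_sites(anc, gsites)
        variants = {
            "01": base,
            "02": _apply_sites(base, [a1]),
            "03": _apply_sites(base, [a2]),
            "04": _apply_sites(base, [a1, a2]),
        }
        for prot, seq in variants.items():
            if grp == g_pair_group and prot == "02":
                # two synonymous (exon-identical) names -> collapses to a G-group
                out.append((parse_allele_name(f"{locus}*{grp}:{prot}:01"), seq))
                out.append((parse_allele_name(f"{locus}*{grp}:{prot}:02"), seq))
            else:
                out.append((parse_allele_name(f"{locus}*{grp}:{prot}"), seq))
    for donor_name, (sites, novel_site) in donors.items():
        seq = _apply_sites(anc, [*sites, novel_site])
        out.append((parse_allele_name(f"{locus}*{donor_name}"), seq))
    return out


def toy_panel_input() -> dict[str, list[tuple[AlleleName, str]]]:
    """Raw (name, exon sequence) lists per locus, before G-group collapsing."""
    rng = np.random.default_rng(_PANEL_SEED)
    anc_b = _ancestral(sum(_EXON_LENGTHS["B"]), rng)
    anc_drb1 = _ancestral(_EXON_LENGTHS["DRB1"][0], rng)
    return {
        "B": _locus_alleles(
            "B", anc_b, _B_GROUPS, _B_SITES, g_pair_group="07",
            donors=_B_DONORS,
        ),
        "DRB1": _locus_alleles(
            "DRB1", anc_drb1, _DRB1_GROUPS, _DRB1_SITES, g_pair_group="15",
            donors=_DRB1_DONORS,
        ),
    }


@dataclass
class ToyWorld:
    ref: ReferenceSet
    cwd: CwdList
    haplotypes: list[Haplotype]
    genotypes: list[tuple[Haplotype, Haplotype]]
    # (haplotype name, locus, exon coord, padded coord) per injected mutation
    novel_truth: list[tuple[str, str, int, int]]


@lru_cache(maxsize=1)
def toy_world() -> ToyWorld:
    """The fixed synthetic validation world (panel, truth, genotypes)."""
    per_locus = toy_panel_input()
    ref = build_reference(
        per_locus,
        loci=[LocusConfig("B", hla_class=1), LocusConfig("DRB1", hla_class=2)],
        exon_lengths=_EXON_LENGTHS,
    )
    cwd = CwdList(
        parse_allele_name(f"{locus}*{grp}:{prot}")
        for locus, groups in (("B", _B_GROUPS), ("DRB1", _DRB1_GROUPS))
        for grp in groups
        for prot in ("01", "02")
    )

    # the ancestral base at a novel site is what every non-donor allele has;
    # the donor's (and the edited haplotype's) base is its transition partner
    anc_drb1_a = ref.allele("DRB1*01:01").exon_sequence[NOVEL_DRB1_A]
    anc_drb1_b = ref.allele("DRB1*15:01").exon_sequence[NOVEL_DRB1_B]
    anc_b = ref.allele("B*08:01").exon_sequence[NOVEL_B]

    h1 = build_haplotype(
        ref,
        {"B": "B*07:02:01G", "DRB1": "DRB1*01:01"},
        edits=[("B", NOVEL_B, _VARIANT[anc_b]),
               ("DRB1", NOVEL_DRB1_A, _VARIANT[anc_drb1_a])],
        name="h1",
    )
    h2 = build_haplotype(
        ref,
        {"B": "B*40:01", "DRB1": "DRB1*15:01"},
        edits=[("DRB1", NOVEL_DRB1_B, _VARIANT[anc_drb1_b])],
        name="h2",
    )
    # Genotype pairings never put a novel haplotype together with a partner
    # from one of that mutation's donor groups — otherwise the novel base
    # would be legitimately attributable to a known allele of the partner's
    # group and the "novelty" would be ill-posed even for a perfect caller.
    h3 = build_haplotype(ref, {"B": "B*07:03", "DRB1": "DRB1*01:02"}, name="h3")
    h4 = build_haplotype(ref, {"B": "B*15:01", "DRB1": "DRB1*07:01"}, name="h4")
    h5 = build_haplotype(ref, {"B": "B*15:02", "DRB1": "DRB1*03:02"}, name="h5")
    h6 = build_haplotype(ref, {"B": "B*44:02", "DRB1": "DRB1*03:03"}, name="h6")
    h7 = build_haplotype(ref, {"B": "B*40:02", "DRB1": "DRB1*15:03"}, name="h7")

    # sanity: every edited haplotype sequence differs from every panel allele
    for hap in (h1, h2):
        for locus, seq in hap.sequences.items():
            if hap.novel_positions.get(locus):
                assert all(
                    rec.exon_sequence != seq for rec in ref.alleles_at(locus)
                ), f"{hap.name}:{locus} edit coincides with a panel allele"

    genotypes = [(h1, h3), (h1, h4), (h2, h5), (h2, h6), (h4, h7), (h5, h6)]
    novel_truth = [
        ("h1", "B", NOVEL_B, ref.exon_to_padded("B", NOVEL_B)),
        ("h1", "DRB1", NOVEL_DRB1_A, ref.exon_to_padded("DRB1", NOVEL_DRB1_A)),
        ("h2", "DRB1", NOVEL_DRB1_B, ref.exon_to_padded("DRB1", NOVEL_DRB1_B)),
    ]
    return ToyWorld(
        ref=ref,
        cwd=cwd,
        haplotypes=[h1, h2, h3, h4, h5, h6, h7],
        genotypes=genotypes,
        novel_truth=novel_truth,
    )
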