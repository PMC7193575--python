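"""Caller tests on clean (error-free) read sets with known truth."""

import numpy as np
import pytest

from hlacall.calling import (
    CallerConfig,
    PhaseOverflow,
    call_sample,
    classify_variants,
    phase_blocks,
)
from hlacall.mapping import map_all
from hlacall.sorting import sort_reads


def tile(seq: str, frag: int = 70, stride: int = 7) -> list[str]:
    """Error-free fragments tiling a haplotype sequence."""
    return [seq[i : i + frag] for i in range(0, len(seq) - frag + 1, stride)]


def call_clean(world, picks: dict[str, tuple[str, str]], stride: int = 7):
    """Run map-sort-call on clean tiled reads from two panel alleles."""
    reads: list[str] = []
    for locus, (a1, a2) in picks.items():
        for name in (a1, a2):
            reads.extend(tile(world.ref.allele(name).exon_sequence, stride=stride))
    mapped = map_all(reads, world.ref)
    groups = sort_reads(mapped, world.ref)
    return call_sample(groups, world.ref, world.cwd)


class TestClassifyVariants:
    def _group(self, world, reads):
        mapped = map_all(reads, world.ref)
        return sort_reads(mapped, world.ref)["B"]

    def test_single_read_variant_is_unsupported(self, world):
        seq = world.ref.allele("B*07:01").exon_sequence
        group = self._group(world, [seq[0:70]])
        cl = classify_variants(group, world.ref)
        assert all(
            not ev.supported
            for by_base in cl.sites.values()
            for ev in by_base.values()
        )

    def test_duplicated_read_variant_is_supported(self, world):
        seq = world.ref.allele("B*07:01").exon_sequence
        group = self._group(world, [seq[0:70]] * 3)
        cl = classify_variants(group, world.ref)
        assert all(
            ev.supported and ev.max_dup == 3
            for by_base in cl.sites.values()
            for ev in by_base.values()
        )

    def test_two_distinct_fragments_support_a_base(self, world):
        seq = world.ref.allele("B*07:01").exon_sequence
        group = self._group(world, [seq[0:70], seq[5:75]])
        cl = classify_variants(group, world.ref)
        # probe a site interior to both reads (terminal observations can be
        # damage-masked and must not be relied on here)
        site = world.ref.exon_to_padded("B", 40)
        (ev,) = cl.sites[site].values()
        assert ev.n_fragments == 2 and ev.supported

    def test_overlapping_mates_count_as_one_fragment(self, world):
        from hlacall.seqio import revcomp

        seq = world.ref.allele("B*07:01").exon_sequence
        frag = seq[0:70]
        group = self._group(world, [frag, revcomp(frag)])  # R1 + R2, same span
        cl = classify_variants(group, world.ref)
        site = world.ref.exon_to_padded("B", 35)  # interior of the fragment
        (ev,) = cl.sites[site].values()
        assert ev.n_fragments == 1 and not ev.supported

    def test_terminal_transition_observation_is_damage_masked(self, world):
        # find a site where the panel is C/T polymorphic, then present the T
        # base at the very start of a read: the observation must be masked
        ref = world.ref
        rec_t = rec_c = None
        for exon_pos in range(40, 230):
            site = ref.exon_to_padded("B", exon_pos)
            by_base = {}
            for rec in ref.alleles_at("B"):
                by_base.setdefault(rec.padded_sequence[site], rec)
            if "C" in by_base and "T" in by_base:
                rec_t, rec_c = by_base["T"], by_base["C"]
                break
        assert rec_t is not None
        read_terminal = rec_t.padded_sequence[site : site + 60]
        read_interior = rec_t.padded_sequence[site - 30 : site + 30]
        group = self._group(world, [read_terminal, read_interior])
        cl = classify_variants(group, ref)
        t_code = 3
        ev = cl.sites[site][t_code]
        # only the interior observation may vote
        assert len(ev.entry_idx) == 1
        entry = group.entries[ev.entry_idx[0]]
        assert entry.start == site - 30


class TestCleanCalls:
    def test_heterozygote_recovers_exact_g_group_names(self, world):
        """Error-free full-coverage reads from two known alleles always
        yield exactly their panel names at maximal resolution."""
        calls = call_clean(
            world, {"B": ("B*07:02:01G", "B*44:02"), "DRB1": ("DRB1*01:01", "DRB1*07:01")}
        )
        assert {str(calls["B"].allele_1), str(calls["B"].allele_2)} == {
            "B*07:02:01G",
            "B*44:02",
        }
        assert {str(calls["DRB1"].allele_1), str(calls["DRB1"].allele_2)} == {
            "DRB1*01:01",
            "DRB1*07:01",
        }
        assert not calls["B"].zygosity_assumed
        assert calls["B"].novel_1 is None and calls["B"].novel_2 is None

    def test_same_group_heterozygote_resolved(self, world):
        calls = call_clean(world, {"B": ("B*07:02:01G", "B*07:03")})
        assert {str(calls["B"].allele_1), str(calls["B"].allele_2)} == {
            "B*07:02:01G",
            "B*07:03",
        }

    def test_homozygote_called_with_assumption_flag(self, world):
        calls = call_clean(world, {"DRB1": ("DRB1*03:01", "DRB1*03:01")})
        call = calls["DRB1"]
        assert str(call.allele_1) == "DRB1*03:01"
        assert str(call.allele_2) == "DRB1*03:01"
        assert call.zygosity_assumed

    def test_empty_locus_is_na(self, world):
        calls = call_clean(world, {"DRB1": ("DRB1*03:01", "DRB1*03:02")})
        assert calls["B"].allele_1 is None and calls["B"].allele_2 is None
        assert calls["B"].evidence["reason"] == "no reads"

    def test_determinism(self, world):
        picks = {"B": ("B*15:01", "B*40:02"), "DRB1": ("DRB1*15:01", "DRB1*03:03")}
        a = call_clean(world, picks)
        b = call_clean(world, picks)
        assert {l: (str(c.allele_1), str(c.allele_2)) for l, c in a.items()} == {
            l: (str(c.allele_1), str(c.allele_2)) for l, c in b.items()
        }

    def test_novel_mutation_detected_on_clean_reads(self, world):
        """A haplotype carrying an engineered point mutation is reported as
        a novel-variant record at the right site.

        The novel site sits in a window invariant between allele groups, so
        which of the two haplotypes carries it cannot be phased from read
        overlap alone — the anchoring allele may be either; the position is
        what must be exact. The partner comes from a group that donates no
        base at the novel site (the same constraint the bundled genotypes
        obey), otherwise the novelty itself would be ill-posed.
        """
        h1 = next(h for h in world.haplotypes if h.name == "h1")
        reads = tile(h1.sequences["B"]) + tile(
            world.ref.allele("B*15:01").exon_sequence
        )
        mapped = map_all(reads, world.ref)
        groups = sort_reads(mapped, world.ref)
        calls = call_sample(groups, world.ref, world.cwd)
        call = calls["B"]
        novel = call.novel_1 or call.novel_2
        assert novel is not None
        expected_site = world.ref.exon_to_padded("B", 400)
        assert novel.positions == [expected_site]
        assert novel.support[expected_site][0] >= 2
        # the two called names still recover both allele groups
        groups_called = {str(call.allele_1).split(":")[0], str(call.allele_2).split(":")[0]}
        assert groups_called == {"B*07", "B*15"}

    def test_three_allele_mixture_overflows_to_na(self, world):
        reads = []
        for name in ("B*07:01", "B*08:01", "B*15:01"):
            reads.extend(tile(world.ref.allele(name).exon_sequence))
        mapped = map_all(reads, world.ref)
        groups = sort_reads(mapped, world.ref)
        calls = call_sample(groups, world.ref, world.cwd)
        assert calls["B"].allele_1 is None and calls["B"].allele_2 is None
        assert calls["B"].evidence["reason"] == "overflow"
        assert "contamination" in calls["B"].evidence["warning"]


def test_phase_blocks_never_exceeds_two(world):
    for picks in (
        {"B": ("B*07:01", "B*44:01")},
        {"B": ("B*15:02", "B*15:03")},
        {"B": ("B*40:01", "B*40:01")},
    ):
        reads = []
        for name in picks["B"]:
            reads.extend(tile(world.ref.allele(name).exon_sequence))
        mapped = map_all(reads, world.ref)
        group = sort_reads(mapped, world.ref)["B"]
        cl = classify_variants(group, world.ref)
        blocks = phase_blocks(group, cl, world.ref, CallerConfig(), world.cwd)
        assert 1 <= len(blocks) <= 2


def test_breadth_gate_returns_na(world):
    # a single short read covers ~9% of the exons: below min_call_breadth
    seq = world.ref.allele("B*07:01").exon_sequence
    mapped = map_all([seq[0:50]], world.ref)
    groups = sort_reads(mapped, world.ref)
    calls = call_sample(groups, world.ref, world.cwd)
    assert calls["B"].allele_1 is None
    assert calls["B"].evidence["reason"] == "breadth"
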