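# Methods

This note documents the models and procedures implemented in `hlacall`,
the parameters that matter, and what the bundled synthetic validation does
and does not establish.

## Mapping reference

The panel holds, per locus, the exon sequences encoding the peptide-binding
groove: exons 2 and 3 for class I loci, exon 2 for class II. Input is one
pre-aligned FASTA per locus (multiple sequence alignment is delegated to an
external aligner; the builder consumes its output). `trim_alignment`
removes columns gapped in ≥ `gap_col_fraction` (default 0.95) of rows —
insertions private to rare non-functional alleles — and columns outside the
exon bounds; rows still carrying gaps afterwards are dropped with a
warning. `collapse_g_groups` merges alleles with identical exon sequence
into one record named after the lowest-numbered member with a `G` suffix
(the G-group convention). Records are padded with `pad_flank` = 100 N on
both ends, and class I records carry a `pad_spacer` = 20 N run between
exons 2 and 3 in place of the (largely unknown) intron. Coordinates are
0-based, half-open, in padded space throughout.

Decoy loci (paralogous non-classical genes) may be included; reads whose
only placements are on decoys are discarded during sorting, which is their
entire purpose.

## Mapping contract

An L-base read is reported iff some gapless placement matches at least
⌈0.99·L⌉ bases (N on either side never matches), and all placements
achieving the read's maximum match count are kept, over both strands and
every allele. Two consequences worth internalising:

* reads shorter than 100 bases must match **exactly**; 100–199 bases allow
  one mismatch. Deaminated reads therefore mostly fail to map — depth, not
  error correction, is how aDNA information is recovered; and a read
  carrying a true novel base maps only because some *other* panel allele
  carries that base at that position, which a dense allele panel almost
  always provides.
* most reads map to several alleles and often several loci. Keeping all
  equally best hits is what makes downstream evidence honest.

Alignment is gapless by design: at ≥99% identity on short reads at most
one indel could fit, exon panels are length-conserved after trimming, and
gaplessness makes the mapper exactly checkable against a brute-force
sliding-window oracle (the test suite does this). Seeding uses a 13-mer
index; a qualifying alignment with m mismatches contains a clean stretch of
≥ (L−m)/(m+1) bases, so seeding is provably lossless whenever that bound
reaches the seed length, and the mapper falls back to exhaustive scanning
when it does not.

Identical read sequences are collapsed before alignment with their
multiplicity kept: on duplicate-preserving aDNA libraries these are PCR
copies of one molecule, later used as evidence that a variant is not a
polymerase/sequencing artifact. Independently, the depth metric
deduplicates by (start, end) placement — two deliberately different
notions of "duplicate".

## Allele calling

The caller re-casts expert manual review as a deterministic algorithm.

**Damage-aware observations.** In reference orientation, deamination
appears as C→T near the left end of a fragment and G→A near its right end,
and PCR replicates it faithfully. Before any counting, a read's T
observation within `damage_window` = 20 bases of its left end is masked at
any site where the panel carries C (symmetrically A near the right end at
panel-G sites). Masked observations vote nowhere but are recorded: a base
seen only in damage geometry can be neither asserted nor refuted.

**Credible variants.** An unmasked base is credible when carried by
`min_support` = 2 position-distinct fragments (overlapping mates and PCR
duplicates count once) or by a read stack with `min_dup` = 2 exact
duplicates. Sites with two credible bases are heterozygous; three credible
bases at one site, or a read incompatible with both haplotype blocks, is
evidence for a third allele and aborts the locus with a contamination
warning (NA).

**Phasing.** Reads carrying credible het-site bases are partitioned by
compatibility within their overlap; a conflict with one side forces the
other. Covered regions not linked by any read cannot be phased by overlap,
so their relative orientation is chosen by a search (exhaustive to 6
components, then greedy largest-first) that minimises, in order: internal
own-read conflicts created by the assignment, blocks unexplained by any
known allele, total mismatches, and non-CWD explanations. This is the
automated counterpart of matching read blocks against the reference
alignment by eye. When a variant lies in a window shared by both allele
groups (as an engineered novel site does), its attribution to one of the
two haplotypes is genuinely undetermined; the reported position is exact
either way.

**Consensus.** Per block and site, a base is emitted only when evidence is
coherent: the block's own reads must agree among themselves; a credible own
base stands; an uncredible own base yields to a credible conflicting one
(gap); a site covered only by unassignable reads is taken only when
unanimous. Under the exact-match mapping regime residual conflicts signal
unresolved heterozygosity, not noise — they are left open, never voted on.

**Matching.** A block's allele identity is decided on the sites its own
reads credibly observed; shared reads establish breadth but cannot
implicate an allele the block never touched. Candidates are screened
against the common-and-well-documented (CWD) catalogue first; candidates
surviving a final confirmation — no conflict with any locus-wide
unanimously observed credible site, damage-masked bases excepted — yield
the call. Resolution rules:

* all candidates one record → full (up to 3rd-field G-group) name;
* several candidates of one allele group → 1st-field name; CWD rank and
  the confirmation step may *remove* candidates (choose between groups)
  but never sharpen within-group resolution;
* candidates from several groups → ambiguous → NA.

**Evidence gates.** Full resolution (2nd field and beyond, novel reports,
homozygosity) requires ≥ `min_full_res_breadth` = 50% of exon sites
covered credibly by ≥2 independent fragments, ≥ `min_full_res_fragments` =
10 fragments in the block, and ≤ `max_own_conflict_frac` = 5% internal
conflict sites; below that the call rounds to the 1st field, and a sparse
group claim must contain a CWD candidate at all. Any call requires
`min_call_breadth` = 20% raw breadth. These gates reproduce the observed
aDNA behaviour — 1st-field calls possible at 1×, 2nd-field calls from
about 5× — as a statement about evidence rather than a depth switch.

**Novel alleles.** A consensus matching no allele anchors at the closest
panel allele (ties anchor at the tied candidates' common prefix and keep
only mismatch sites shared by all of them). Each novel position must be
credible and unanimous within the block; remaining mismatches are treated
as artifacts, removed, and matching falls back to the best known allele.
With a CWD list active, novel reports must anchor at a CWD-covered name —
the same prior that drives CWD-first matching, applied to novelty claims.

**Zygosity.** One block covering ≥ `min_homozygous_breadth` = 80% of exon
sites credibly, with ≥10 fragments and no unexplained variation, is called
homozygous with an explicit `zygosity_assumed` flag. Distinguishing true
homozygosity from allelic dropout is impossible on sparse aDNA; the
bundled validation experiment therefore exports the assumed second slot as
NA, and downstream users can make their own choice from the flag.

## Ancient-DNA simulator

Fragments are drawn per locus until their cumulative length reaches
depth × locus length (depth = expected fragment coverage), with lognormal
lengths (mean 70 bp, sd 20 bp, truncated to 40–140 bp; empirical UDG
libraries report per-sample means of ~47–101 bp) and uniform placement.
Each fragment is sequenced from a uniformly random strand; deamination is
applied to the template (C→T at the 5′ end, G→A at the 3′ end, probability
d·decay^i at distance i, defaults d5 = d3 = 0.2 and decay = 0.5 — the
non-UDG regime with ~20% terminal misincorporation; UDG-treated material
sits at ≤3%; an explicit per-position vector may replace the geometric
model). Paired 75 bp reads are cut from both fragment ends (short
fragments yield fully overlapping mates), whole pairs are PCR-duplicated
with a geometric tail (rate 0.1), and a uniform 0.1% per-base error is
added per copy. Seeded runs are byte-identical. No microbial or human
contamination is simulated — every read derives from the two truth
haplotypes, as in a capture experiment on an uncontaminated sample.

`profile_damage` recovers the terminal misincorporation curves from the
fragment records (pre- vs post-damage), closing a parameter-recovery loop
the tests assert to within 3σ.

## The synthetic validation world

Two target loci — "B" (class I, exons 270+276 bp) and "DRB1" (class II,
exon 270 bp) — with five 1st-field groups each, four alleles per group,
one exon-identical pair per locus that collapses into a G-group, and
free-standing rare "donor" alleles (~22–24 records per locus). The layered
site structure imitates real HLA polymorphism: eight spread private sites
per group, within-group allele sites within one read length of each other
(so same-group heterozygotes are phaseable by overlapping reads).

Seven haplotypes are combined into six heterozygous diploid genotypes;
three "de-novo" point mutations are injected into two haplotypes (one at
each locus of the first, one at the second's DRB1). Because sub-100 bp
reads must match the panel exactly, a novel base is only observable if
some other allele carries it: each mutation site is the private variant of
*two* donor alleles from distinct groups, inside a window otherwise
invariant between the source and donor groups. Reads spanning the mutation
map perfectly onto the donors, the assembled consensus matches nothing —
the novel-allele signature — while a sparse consensus matches both donors
at once and is reported NA rather than as a wrong rare allele. Genotype
pairings never combine a novel haplotype with a partner from one of that
mutation's donor groups; otherwise the novelty would be ill-posed even for
a perfect caller. All positions and pairings are fixed constants, checked
by assertions at import.

What a green validation run does establish: the full pipeline recovers
every resolvable genotype without a single wrong allele call across 20
simulation seeds (3,000 samples), detects all injected mutations at the
correct positions from 5–10× up, and reproduces the depth-resolution
pattern. What it does not establish: performance on the real allele panel
(thousands of alleles, non-transition variants, unequal allele
divergence), real damage profiles (the geometric decay is a stylised
Briggs-type model), contamination robustness (not simulated), or
library-preparation artefacts beyond flat error and duplication.

## Evaluation measures

Success rate = called alleles / assayed alleles (two per locus and
sample), where a slot counts at field level k only if the name carries ≥ k
fields; ambiguous calls are NA and remain in the denominator. Accuracy =
correct / (correct + incorrect) with NA slots excluded from both sides;
genotypes are compared as multisets (the pairing maximising matches).
Agreement between two call sets excludes slots NA in either. A 1st-field
call compared at the 2nd field counts as NA, not as incorrect.

## Population genetics

Analyses keep calls at ≥ 2nd-field resolution (configurable) and drop
individuals incompletely typed at the loci under study. Haplotype
frequencies come from the standard genotype-phase EM (ambiguous genotypes
distributed over compatible haplotype pairs proportional to current
frequency products; tolerance 1e−8, ≤1000 iterations, 10 restarts keeping
the best likelihood, monotone likelihood asserted every step, equal-
likelihood disagreeing restarts flagged `multimodal`). Pairwise LD:
Dᵢⱼ = hᵢⱼ − pᵢqⱼ normalised by its sign-dependent maximum and averaged
with weights pᵢqⱼ (Hedrick's D′), and Wn = √(χ²/(2N·(min(k,l)−1)))
computed over 2N estimated haplotypes — the normalisation validated
against the perfect-LD limit D′ = Wn = 1. The overall-LD test compares
2·(logL_EM − logL_independence) against a permutation null built by
shuffling one locus's genotypes across individuals, with
p = (1 + #{perm ≥ obs}) / (n_perm + 1); its type-I error at α = 0.05 is
checked over 200 null replicates.

## Numerical and interface choices

* Allele-name fields keep leading zeros textually but compare numerically
  (`A*01:01` equals `A*1:1`); the `HLA-` prefix is optional on input and
  emitted by `format()`.
* Minimum read length 25 bp, matching standard adapter-trimming floors.
* `min_score` guards the identity threshold against float noise:
  ⌈0.99·100⌉ is 99, not 100.
* Ties everywhere (candidate order, phasing seeds, orientation search) are
  broken deterministically; identical inputs and configuration give
  identical calls.
* SAM import recovers read sequences and re-derives placements internally,
  so imported and internally mapped reads obey the same equally-best
  contract regardless of what the external mapper chose to report.
* Genotype tables are TSV: `sample_id`, then `<locus>_1`, `<locus>_2`
  per locus, `NA` for no call.

## Known limitations

* Novel variants of alleles outside the CWD catalogue are not reported as
  novel (they surface as NA or rounded calls) when a CWD list is active.
* Attribution of an unlinkable novel site to one of two haplotypes is
  arbitrary; positions are exact, the anchoring allele may be the
  partner's.
* Homozygosity is an assumption, never an observation; at 5× and below the
  assumed second slot is best treated as missing.
* The mapper is gapless; indel alleles would need the reserved gapped mode.
* False novel flags can appear at asymmetric coverage (one haplotype
  locally invisible); they anchor at the correct allele and carry their
  supporting evidence for review.
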