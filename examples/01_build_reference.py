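"""Build a padded, G-group-collapsed mapping panel from exon alleles.

The mapping reference holds, per locus, the exon sequences coding for the
peptide-binding groove: exons 2+3 for class I, exon 2 for class II. Alleles
identical across those exons collapse into one G-group record; every record
is padded with 100 N on each flank (and class I gets a 20 N spacer between
the exons), so reads running off an exon edge still have reference to sit
on without inventing intron sequence.
"""

from hlacall import build_reference
from hlacall.nomenclature import parse_allele_name
from hlacall.reference import LocusConfig, write_reference
from hlacall.synthetic import toy_panel_input

per_locus = toy_panel_input()  # {locus: [(AlleleName, exon sequence), ...]}
print("input allele names per locus:")
for locus, alleles in per_locus.items():
    print(f"  {locus}: {len(alleles)} names")

ref = build_reference(
    per_locus,
    loci=[LocusConfig("B", hla_class=1), LocusConfig("DRB1", hla_class=2)],
    exon_lengths={"B": [270, 276], "DRB1": [270]},
)

for locus in ref.target_loci:
    records = ref.alleles_at(locus)
    g_groups = [r for r in records if len(r.members) > 1]
    print(
        f"{locus}: {len(records)} records after collapsing, "
        f"padded length {ref.locus_length(locus)} "
        f"(exon spans {ref.exon_spans(locus)})"
    )
    for rec in g_groups:
        print(
            f"  G-group {rec.name} merges "
            + ", ".join(str(m) for m in rec.members)
        )

write_reference(ref, "/tmp/panel.fasta", "/tmp/panel.tsv")
print("wrote /tmp/panel.fasta + /tmp/panel.tsv (sidecar with loci/members)")

# A class I record is 100 N + exon2 + 20 N + exon3 + 100 N:
rec = ref.allele("B*07:02:01G")
assert len(rec.padded_sequence) == 100 + 270 + 20 + 276 + 100
print(f"B*07:02:01G padded length: {len(rec.padded_sequence)} = 100+270+20+276+100")
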