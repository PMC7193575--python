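import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlacall.nomenclature import parse_allele_name
from hlacall.reference import LocusConfig, ReferenceSet, build_reference
from hlacall.synthetic import toy_world

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_exon(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def world():
    """The bundled synthetic two-locus validation world."""
    return toy_world()


@pytest.fixture(scope="session")
def small_ref() -> ReferenceSet:
    """A 30-allele two-locus reference for mapper oracle tests.

    Alleles of a locus are mutated copies of one ancestral exon, so reads
    map ambiguously across alleles the way HLA reads do; one class I locus
    exercises the internal N spacer.
    """
    rng = np.random.default_rng(7)
    per_locus = {}
    # class I locus: exons 120 + 130; class II locus: exon 150
    for locus, lengths, n_alleles in (("A", [120, 130], 18), ("DQB1", [150], 12)):
        total = sum(lengths)
        anc = random_exon(rng, total)
        alleles = []
        seen = {anc}
        for i in range(n_alleles):
            seq = list(anc)
            while True:
                n_mut = int(rng.integers(1, 6))
                for _ in range(n_mut):
                    pos = int(rng.integers(0, total))
                    seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                s = "".join(seq)
                if s not in seen:
                    seen.add(s)
                    break
            alleles.append(
                (parse_allele_name(f"{locus}*{i // 4 + 1:02d}:{i % 4 + 1:02d}"), s)
            )
        per_locus[locus] = alleles
    return build_reference(
        per_locus,
        loci=[LocusConfig("A", hla_class=1), LocusConfig("DQB1", hla_class=2)],
        exon_lengths={"A": [120, 130], "DQB1": [150]},
    )
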