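import numpy as np
import pytest

from plastintron.annotation_io import AnnotatedGenome, GeneModel, IntronRecord
from plastintron.annotation_io import _assign_ordinals


def make_genome(genes_spec, length=None, tag="Toy", seq=None):
    """Assemble a toy AnnotatedGenome from (name, kind, strand, exons,
    intron_intervals) tuples over an A-filled (or given) sequence."""
    end = max(e for *_, exons, _ in genes_spec for _, e in exons)
    L = length or end + 10
    sequence = seq or ("A" * L)
    genes = []
    for name, kind, strand, exons, intron_ivs in genes_spec:
        g = GeneModel(name=name, kind=kind, strand=strand, exons=list(exons))
        g.introns = [
            IntronRecord(host_gene=name, ordinal=0, interval=iv,
                         sequence=sequence[iv[0]: iv[1]])
            for iv in intron_ivs
        ]
        genes.append(g)
    genome = AnnotatedGenome(id=tag, species_tag=tag, sequence=sequence,
                             genes=genes)
    _assign_ordinals(genome)
    return genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fixture_groups():
    from plastintron.site_mapping import load_site_fixture

    return load_site_fixture()
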