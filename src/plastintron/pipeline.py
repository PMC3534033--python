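"""End-to-end glue: genomes -> aligned sites -> cognate groups.

Per gene, ortholog protein sequences are gathered across the genomes,
aligned (star MSA by default, or externally supplied alignments), every
intron insertion site projected to (column, phase), and cognate sites
clustered. This is the common coordinate frame behind the catalog, the
sharing matrix and the Dollo mapping.
"""
from __future__ import annotations

from typing import Mapping, Optional

from .alignment import MultipleAlignment, ScoringScheme, star_msa
from .annotation_io import AnnotatedGenome
from .site_mapping import (AlignedSite, SiteGroup, cluster_cognate_sites,
                           project_site)

__all__ = ["sites_from_genomes"]


def sites_from_genomes(
    genomes: Mapping[str, AnnotatedGenome],
    scheme: Optional[ScoringScheme] = None,
    alignments: Optional[Mapping[str, MultipleAlignment]] = None,
    keep_distinct=(),
) -> list[SiteGroup]:
    """Project and cluster every intron insertion site across genomes.

    ``alignments`` may supply precomputed per-gene alignments (rows named by
    species tag); genes not covered are aligned with the in-repo star MSA.
    """
    gene_names: list[str] = []
    for g in genomes.values():
        for gene in g.genes:
            if gene.name not in gene_names:
                gene_names.append(gene.name)

    sites: list[AlignedSite] = []
    for gname in gene_names:
        carriers = {
            tag: genome for tag, genome in genomes.items()
            if any(x.name == gname for x in genome.genes)
        }
        with_introns = {
            tag: genome.gene(gname) for tag, genome in carriers.items()
            if genome.gene(gname).introns
        }
        if not with_introns:
            continue
        if alignments and gname in alignments:
            msa = alignments[gname]
        elif len(carriers) == 1:
            (tag, genome), = carriers.items()
            prot = genome.protein_sequence(genome.gene(gname))
            msa = MultipleAlignment([tag], [prot])
        else:
            tags = sorted(carriers)
            msa = star_msa(
                [carriers[t].protein_sequence(carriers[t].gene(gname))
                 for t in tags],
                ids=tags, scheme=scheme,
            )
        for tag, gene in with_introns.items():
            for intron in gene.introns:
                sites.append(project_site(intron, msa, tag))
    return cluster_cognate_sites(sites, keep_distinct=keep_distinct)
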