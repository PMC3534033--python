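"""Annotated plastid genome I/O and partition accounting.

Genomes are held with 0-based half-open intervals on the forward strand
(strand recorded per gene); user-facing reports use 1-based inclusive
coordinates. Introns may nest (twintrons): a nested intron is attached as a
child of its parent and a nested stack counts as a single insertion site.

Partition accounting classifies every genomic position exactly once with
precedence intron > exon > intergenic, so gene_bp + intron_bp +
intergenic_bp always equals the genome length. Intron-encoded ORFs
(maturases) are excluded from gene counts and gene bp — their positions are
intronic — and reported separately.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

GENE_KINDS = ("protein", "tRNA", "rRNA", "ORF")

__all__ = [
    "IntronRecord",
    "GeneModel",
    "AnnotatedGenome",
    "GenomePartition",
    "StructuralError",
    "parse_genome_record",
    "partition_stats",
    "extract_introns",
    "write_gff3",
    "load_table1",
    "partition_report",
    "reverse_complement_genome",
]


class StructuralError(ValueError):
    """An annotation violates genome structure (e.g. intron outside its host)."""


@dataclass
class IntronRecord:
    """One intron insertion, possibly carrying nested internal introns."""

    host_gene: str
    ordinal: int  # 1-based, 5'->3' along the transcript
    interval: tuple[int, int]  # genomic, 0-based half-open, forward strand
    sequence: str  # transcript orientation
    phase: Optional[int] = None  # {0,1,2} for protein hosts, else None
    cds_offset: Optional[int] = None  # coding nt 5' of the insertion point
    children: list["IntronRecord"] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def site_id(self) -> str:
        return f"{self.host_gene}.{self.ordinal}"


@dataclass
class GeneModel:
    name: str
    kind: str  # protein | tRNA | rRNA | ORF
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]]  # genomic intervals, ascending
    duplicate_group: Optional[str] = None
    introns: list[IntronRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise StructuralError(f"overlapping exons in {self.name}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def transcript_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class AnnotatedGenome:
    id: str
    species_tag: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    circular: bool = True
    origin_offset: int = 0  # rotation applied at parse time, for reporting

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def at_content(self) -> float:
        s = self.sequence.upper()
        at = s.count("A") + s.count("T") + s.count("U")
        return 100.0 * at / len(s) if s else 0.0

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def coding_sequence(self, gene: GeneModel) -> str:
        parts = [self.sequence[s:e] for s, e in gene.exons]
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def protein_sequence(self, gene: GeneModel) -> str:
        cds = self.coding_sequence(gene)
        return str(Seq(cds[: len(cds) - len(cds) % 3]).translate()).rstrip("*")


@dataclass
class GenomePartition:
    species_tag: str
    total_bp: int
    gene_bp: int
    intergenic_bp: int
    intron_bp: int
    counts: dict = field(default_factory=dict)

    @property
    def coding_ratio(self) -> float:
        return 100.0 * self.gene_bp / self.total_bp

    @property
    def intergenic_ratio(self) -> float:
        return 100.0 * self.intergenic_bp / self.total_bp

    @property
    def intronic_ratio(self) -> float:
        return 100.0 * self.intron_bp / self.total_bp

    def conserves(self) -> bool:
        return self.gene_bp + self.intergenic_bp + self.intron_bp == self.total_bp


# ---------------------------------------------------------------------------
# parsing


def _introns_from_exon_gaps(gene: GeneModel, sequence: str) -> list[IntronRecord]:
    """Derive introns as the gaps between consecutive exons (genomic order)."""
    out = []
    for (s0, e0), (s1, e1) in zip(gene.exons, gene.exons[1:]):
        if s1 > e0:
            seq = sequence[e0:s1]
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            out.append(
                IntronRecord(
                    host_gene=gene.name, ordinal=0, interval=(e0, s1), sequence=seq
                )
            )
    return out


def _attach_nested(parents: list[IntronRecord], nested: list[IntronRecord]) -> None:
    """Attach each nested intron to the innermost enclosing intron."""
    for child in sorted(nested, key=lambda i: i.length, reverse=True):
        host = None
        stack = list(parents)
        while stack:
            cand = stack.pop()
            s, e = cand.interval
            if s < child.interval[0] and child.interval[1] < e:
                host = cand
                stack = list(cand.children)
        if host is None:
            raise StructuralError(
                f"nested intron {child.interval} has no enclosing intron"
            )
        host.children.append(child)
    for p in parents:
        p.children.sort(key=lambda i: i.interval)


def _kind_from_feature(ftype: str, name: str) -> Optional[str]:
    if ftype == "CDS":
        return "ORF" if name.lower().startswith("orf") else "protein"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        return "rRNA"
    return None


def _parse_flatfile(path: Path, fmt: str) -> AnnotatedGenome:
    rec = SeqIO.read(str(path), fmt)
    circular = rec.annotations.get("topology", "circular") == "circular"
    genome = AnnotatedGenome(
        id=rec.id, species_tag=rec.id, sequence=str(rec.seq).upper(), circular=circular
    )
    explicit_introns: list[tuple[int, int, int]] = []  # (start, end, strand)
    for feat in rec.features:
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        kind = _kind_from_feature(feat.type, name)
        if feat.type == "intron":
            explicit_introns.append(
                (int(feat.location.start), int(feat.location.end))
            )
            continue
        if kind is None:
            continue
        exons = sorted(
            (int(p.start), int(p.end)) for p in feat.location.parts
        )
        strand = "-" if feat.location.strand == -1 else "+"
        dup = feat.qualifiers.get("duplicate_group", [None])[0]
        gene = GeneModel(name=name, kind=kind, strand=strand, exons=exons,
                         duplicate_group=dup)
        gene.introns = _introns_from_exon_gaps(gene, genome.sequence)
        genome.genes.append(gene)
    # explicit intron features refine nesting: an intron feature strictly
    # inside a derived intron becomes its child
    for s, e in explicit_introns:
        for gene in genome.genes:
            for top in gene.introns:
                ts, te = top.interval
                if ts < s and e < te:
                    seq = genome.sequence[s:e]
                    if gene.strand == "-":
                        seq = str(Seq(seq).reverse_complement())
                    _attach_nested(
                        [top],
                        [IntronRecord(gene.name, 0, (s, e), seq)],
                    )
    _assign_ordinals(genome)
    return genome


def _parse_gff3(gff_path: Path, fasta_path: Path) -> AnnotatedGenome:
    import gffutils

    rec = SeqIO.read(str(fasta_path), "fasta")
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genome = AnnotatedGenome(
        id=rec.id, species_tag=rec.id, sequence=str(rec.seq).upper()
    )
    gene_by_id: dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        name = gf.attributes.get("Name", [gf.id])[0]
        kind = gf.attributes.get("gene_kind", ["protein"])[0]
        dup = gf.attributes.get("duplicate_group", [None])[0]
        exons = sorted(
            (ef.start - 1, ef.end)
            for ef in db.children(gf, featuretype="exon")
        )
        if not exons:
            exons = [(gf.start - 1, gf.end)]
        gene = GeneModel(name=name, kind=kind, strand=gf.strand, exons=exons,
                         duplicate_group=dup)
        genome.genes.append(gene)
        gene_by_id[gf.id] = gene

    # introns: Parent may be a gene (top level) or another intron (nested)
    intron_feats = list(db.features_of_type("intron"))
    by_id = {f.id: f for f in intron_feats}
    tops: dict[str, list[IntronRecord]] = {}
    nested: dict[str, list[IntronRecord]] = {}
    rec_by_fid: dict[str, IntronRecord] = {}
    for f in intron_feats:
        parent = f.attributes["Parent"][0]
        iv = (f.start - 1, f.end)
        host_gene_id = parent
        while host_gene_id in by_id:  # walk up to the owning gene
            host_gene_id = by_id[host_gene_id].attributes["Parent"][0]
        gene = gene_by_id[host_gene_id]
        gs, ge = gene.span
        if not (gs <= iv[0] and iv[1] <= ge):
            raise StructuralError(
                f"intron {f.id} at {iv} outside host gene {gene.name}"
            )
        seq = genome.sequence[iv[0]: iv[1]]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        ir = IntronRecord(gene.name, 0, iv, seq)
        rec_by_fid[f.id] = ir
        if parent in by_id:
            nested.setdefault(host_gene_id, []).append(ir)
        else:
            tops.setdefault(host_gene_id, []).append(ir)
    for gid, gene in gene_by_id.items():
        gene.introns = sorted(tops.get(gid, []), key=lambda i: i.interval)
        if gid in nested:
            _attach_nested(gene.introns, nested[gid])
    _assign_ordinals(genome)
    return genome


def parse_genome_record(path, fmt: str = "genbank",
                        fasta: Optional[str] = None,
                        species_tag: Optional[str] = None) -> AnnotatedGenome:
    """Parse an annotated genome record.

    Parameters
    ----------
    path:
        The GenBank/EMBL flat file, or the GFF3 file when ``fmt`` is ``gff3``.
    fmt:
        One of ``genbank``, ``embl``, ``gff3``.
    fasta:
        The companion FASTA (required for ``gff3``).
    species_tag:
        Short tag (e.g. ``Maen``) used in site identifiers; defaults to the
        record id.
    """
    path = Path(path)
    if fmt in ("genbank", "embl"):
        genome = _parse_flatfile(path, fmt)
    elif fmt == "gff3":
        if fasta is None:
            raise ValueError("gff3 format requires a companion fasta path")
        genome = _parse_gff3(path, Path(fasta))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if species_tag:
        genome.species_tag = species_tag
    _validate(genome)
    return genome


def _validate(genome: AnnotatedGenome) -> None:
    for gene in genome.genes:
        gs, ge = gene.span
        if gs < 0 or ge > genome.length:
            raise StructuralError(f"gene {gene.name} outside genome bounds")
        if gene.kind == "protein" and gene.coding_length % 3 != 0:
            # e.g. a small unannotated exon may be hiding in a divergent gene
            warnings.warn(
                f"coding length of {gene.name} not divisible by 3",
                stacklevel=2,
            )


def _assign_ordinals(genome: AnnotatedGenome) -> None:
    """Number top-level introns 1..n in transcript (5'->3') order and compute
    phases from the coding offset of each insertion point."""
    for gene in genome.genes:
        exon_bounds = gene.exons
        # coding nt upstream (transcript orientation) of each genomic position
        def cds_offset_at(pos: int) -> int:
            if gene.strand == "+":
                return sum(
                    min(e, pos) - s for s, e in exon_bounds if s < pos
                )
            return sum(
                e - max(s, pos) for s, e in exon_bounds if e > pos
            )

        tops = sorted(gene.introns, key=lambda i: i.interval)
        if gene.strand == "-":
            tops = tops[::-1]
        for k, intron in enumerate(tops, start=1):
            intron.ordinal = k
            point = intron.interval[1] if gene.strand == "-" else intron.interval[0]
            off = cds_offset_at(point)
            intron.cds_offset = off
            intron.phase = off % 3 if gene.kind in ("protein", "ORF") else None
        gene.introns = tops


def extract_introns(genome: AnnotatedGenome) -> list[IntronRecord]:
    """All top-level introns, grouped by gene, ordinals in transcript order.

    Nested (twintron-internal) introns remain accessible via ``children`` and
    are not listed as separate insertion sites.
    """
    out: list[IntronRecord] = []
    for gene in genome.genes:
        for intron in gene.introns:
            s, e = intron.interval
            in_gap = any(
                e0 == s and s1 == e
                for (s0, e0), (s1, e1) in zip(gene.exons, gene.exons[1:])
            )
            if not in_gap:
                raise StructuralError(
                    f"intron {intron.site_id} at {intron.interval} is not "
                    f"flanked by exons of {gene.name}"
                )
            out.append(intron)
    return out


# ---------------------------------------------------------------------------
# partition accounting


def _intronic_orf_names(genome: AnnotatedGenome) -> set[str]:
    """Genes wholly contained in an intron interval (maturase ORFs)."""
    intron_ivs = [
        i.interval for g in genome.genes for i in g.introns
    ]
    out = set()
    for gene in genome.genes:
        gs, ge = gene.span
        if any(s <= gs and ge <= e for s, e in intron_ivs):
            out.add(gene.name)
    return out


def partition_stats(genome: AnnotatedGenome) -> GenomePartition:
    """Classify every position (intron > exon > intergenic) and count genes
    under the publication rules: duplicated genes counted once, free-standing
    ORFs excluded from gene counts, intronic ORFs reported separately, nested
    twintron stacks counted as single insertion sites."""
    mask = np.zeros(genome.length, dtype=np.uint8)  # 0 intergenic 1 gene 2 intron
    intronic_orfs = _intronic_orf_names(genome)
    for gene in genome.genes:
        if gene.name in intronic_orfs:
            continue
        for s, e in gene.exons:
            mask[s:e] = np.maximum(mask[s:e], 1)
    n_sites = 0
    for gene in genome.genes:
        for intron in gene.introns:
            s, e = intron.interval
            mask[s:e] = 2
            n_sites += 1  # nested children do not add sites

    seen_dup: set[str] = set()
    counts = {"total": 0, "protein": 0, "tRNA": 0, "rRNA": 0}
    for gene in genome.genes:
        if gene.name in intronic_orfs or gene.kind == "ORF":
            continue
        if gene.duplicate_group:
            if gene.duplicate_group in seen_dup:
                continue
            seen_dup.add(gene.duplicate_group)
        counts["total"] += 1
        if gene.kind in counts:
            counts[gene.kind] += 1
    counts["insertion_sites"] = n_sites
    counts["intron_orfs"] = len(intronic_orfs)

    gene_bp = int((mask == 1).sum())
    intron_bp = int((mask == 2).sum())
    return GenomePartition(
        species_tag=genome.species_tag,
        total_bp=genome.length,
        gene_bp=gene_bp,
        intergenic_bp=genome.length - gene_bp - intron_bp,
        intron_bp=intron_bp,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# writing & reports


def write_gff3(genome: AnnotatedGenome, gff_path, fasta_path) -> None:
    """Write the genome as GFF3 + FASTA (1-based inclusive coordinates)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]

    def feat(ftype, s, e, strand, attrs):
        a = ";".join(f"{k}={v}" for k, v in attrs.items())
        lines.append(
            f"{genome.id}\tplastintron\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{a}"
        )

    def emit_intron(intron: IntronRecord, fid: str, parent: str, strand: str):
        feat("intron", intron.interval[0], intron.interval[1], strand,
             {"ID": fid, "Parent": parent})
        for j, child in enumerate(intron.children, 1):
            emit_intron(child, f"{fid}.i{j}", fid, strand)

    for gi, gene in enumerate(genome.genes, 1):
        gid = f"gene{gi}"
        gs, ge = gene.span
        attrs = {"ID": gid, "Name": gene.name, "gene_kind": gene.kind}
        if gene.duplicate_group:
            attrs["duplicate_group"] = gene.duplicate_group
        feat("gene", gs, ge, gene.strand, attrs)
        for ei, (s, e) in enumerate(gene.exons, 1):
            feat("exon", s, e, gene.strand, {"ID": f"{gid}.e{ei}", "Parent": gid})
        for ii, intron in enumerate(sorted(gene.introns, key=lambda i: i.interval), 1):
            emit_intron(intron, f"{gid}.i{ii}", gid, gene.strand)

    Path(gff_path).write_text("\n".join(lines) + "\n")
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i: i + 70] + "\n")


def reverse_complement_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """The same genome read from the other strand (coordinate mirror)."""
    L = genome.length
    rc = str(Seq(genome.sequence).reverse_complement())

    def flip(iv: tuple[int, int]) -> tuple[int, int]:
        return (L - iv[1], L - iv[0])

    def flip_intron(i: IntronRecord) -> IntronRecord:
        return IntronRecord(
            host_gene=i.host_gene, ordinal=0, interval=flip(i.interval),
            sequence=i.sequence, children=[flip_intron(c) for c in i.children],
        )

    genes = []
    for g in genome.genes:
        ng = GeneModel(
            name=g.name, kind=g.kind, strand="-" if g.strand == "+" else "+",
            exons=[flip(e) for e in g.exons], duplicate_group=g.duplicate_group,
        )
        ng.introns = [flip_intron(i) for i in g.introns]
        genes.append(ng)
    out = AnnotatedGenome(
        id=genome.id, species_tag=genome.species_tag, sequence=rc,
        genes=genes, circular=genome.circular,
    )
    _assign_ordinals(out)
    return out


def load_table1(path=None) -> pd.DataFrame:
    """Published genome-feature table (sizes, ratios, counts) as a DataFrame
    indexed by species tag."""
    if path is None:
        from importlib.resources import files

        path = files("plastintron.data") / "table1_genome_features.tsv"
    return pd.read_csv(str(path), sep="\t", index_col="tag")


def table1_partitions(path=None) -> list[GenomePartition]:
    """GenomePartition objects reproducing the published size partitions."""
    df = load_table1(path)
    out = []
    for tag, row in df.iterrows():
        out.append(
            GenomePartition(
                species_tag=tag,
                total_bp=int(row.total_bp),
                gene_bp=int(row.genes_bp),
                intergenic_bp=int(row.intergenic_bp),
                intron_bp=int(row.introns_bp),
                counts={
                    "total": int(row.genes_total),
                    "protein": int(row.protein_coding),
                    "tRNA": int(row.trnas),
                    "rRNA": int(row.rrnas),
                    "insertion_sites": int(row.insertion_sites),
                    "intron_orfs": int(row.intron_orfs),
                },
            )
        )
    return out


def partition_report(parts: Iterable[GenomePartition]) -> pd.DataFrame:
    """TSV-ready report mirroring the published feature-table layout."""
    rows = []
    for p in parts:
        rows.append(
            {
                "tag": p.species_tag,
                "total_bp": p.total_bp,
                "genes_bp": p.gene_bp,
                "intergenic_bp": p.intergenic_bp,
                "introns_bp": p.intron_bp,
                "coding_pct": round(p.coding_ratio, 1),
                "intergenic_pct": round(p.intergenic_ratio, 1),
                "intronic_pct": round(p.intronic_ratio, 1),
                **{k: v for k, v in p.counts.items()},
            }
        )
    return pd.DataFrame(rows).set_index("tag")
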