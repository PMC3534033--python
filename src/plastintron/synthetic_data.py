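"""Synthetic clades of annotated plastid genomes with known intron histories.

The generator walks a rooted species tree from the root: on each branch,
new insertion sites arise as a Poisson draw (per-branch intensity, so
"burst" branches are just branches with higher intensity), existing sites
are lost with a per-branch probability, and existing sites may acquire a
nested internal intron (twintron formation). Each site carries a single
intron sequence generated to satisfy the euglenid group III consensus
(5'-NUNNG start, U-rich interior, 3' pseudo-domain VI) or a longer group
II-style sequence with the same 3' pseudo-domain. At the leaves, genomes
are assembled with AT-rich exons and intergenic spacers (euglenid plastids
run near 70% A+T) and the full gain/loss/nesting truth is recorded.

Exon sequences are shared across the clade (no substitution process), so
ortholog alignments are exact; the generator exercises coordinate handling,
clustering and reconstruction, not alignment robustness to divergence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .annotation_io import AnnotatedGenome, GeneModel, IntronRecord
from .phylo_mapping import load_tree
from .site_mapping import SiteGroup, load_site_fixture
from .twintron import TwintronReference

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_clade",
    "generate_intron_sequence",
    "build_paper_fixture",
    "build_twintron_cohort",
    "TwintronCohort",
]

_DNA = np.array(list("ACGT"))
# euglenid-style 70% A+T background
_AT_RICH = np.array([0.35, 0.15, 0.15, 0.35])

DEFAULT_TREE = "((((Egra,Elon)n1,Maen)n2,Evir)n3,Egym)root;"
DEFAULT_GENES = (
    ("psbA", 120), ("psbC", 150), ("rbcL", 160), ("rpoB", 200),
    ("rpoC1", 220), ("rps3", 80), ("tufA", 130), ("atpB", 140),
)


@dataclass
class SimulationConfig:
    """Study conditions for a simulated clade.

    ``gain_intensity`` is the expected number of new insertion sites per
    branch; a mapping keyed by child-clade label overrides the default on
    designated (e.g. burst) branches.
    """

    tree: str = DEFAULT_TREE
    gain_intensity: float | dict = 3.0
    loss_prob: float = 0.0  # per existing site per branch
    nesting_prob: float = 0.0  # twintron formation per site per branch
    genes: Sequence[tuple[str, int]] = DEFAULT_GENES  # (name, n_codons)
    group3_fraction: float = 0.7
    group3_len: tuple[int, int] = (60, 140)
    group2_len: tuple[int, int] = (250, 500)
    spacer_len: tuple[int, int] = (60, 200)
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene set must be non-empty")
        if not 0 <= self.loss_prob <= 1 or not 0 <= self.nesting_prob <= 1:
            raise ValueError("probabilities must lie in [0,1]")

    def intensity_for(self, branch_label: str) -> float:
        if isinstance(self.gain_intensity, dict):
            return float(self.gain_intensity.get(
                branch_label, self.gain_intensity.get("default", 0.0)))
        return float(self.gain_intensity)


@dataclass
class SiteTruth:
    site_key: str
    gene: str
    codon: int  # 0-based residue index of the interrupted codon
    phase: int
    gain_branch: str  # child-node label of the branch the site arose on
    loss_branches: list[str] = field(default_factory=list)
    nestings: list[str] = field(default_factory=list)  # branches adding internals
    present_in: set = field(default_factory=set)


@dataclass
class SimulationTruth:
    sites: list[SiteTruth]
    species: list[str]

    def expected_sharing(self) -> np.ndarray:
        """The sharing matrix a perfect site recovery would produce."""
        idx = {s: i for i, s in enumerate(self.species)}
        m = np.zeros((len(self.species),) * 2, dtype=int)
        for st in self.sites:
            tags = sorted(st.present_in)
            for a in tags:
                m[idx[a], idx[a]] += 1
            for i, a in enumerate(tags):
                for b in tags[i + 1:]:
                    m[idx[a], idx[b]] += 1
                    m[idx[b], idx[a]] += 1
        return m

    def branch_gains(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for st in self.sites:
            out[st.gain_branch] = out.get(st.gain_branch, 0) + 1
        return out


def _rand_seq(rng: np.random.Generator, n: int,
              probs: np.ndarray = _AT_RICH) -> str:
    return "".join(rng.choice(_DNA, size=n, p=probs))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_intron_sequence(kind: str, length: int,
                             rng: Optional[np.random.Generator] = None,
                             seed: Optional[int] = None,
                             u_fraction: float = 0.45) -> str:
    """Generate an intron satisfying the scanned consensuses.

    group_III (>= 30 nt): starts N-T-N-N-G, U(T)-rich interior, ends with a
    planted pseudo-domain VI (Watson-Crick stem, 4-nt loop, bulged A, 4-nt
    tail). group_II (>= 200 nt): canonical GTGCG start, unbiased interior,
    same planted 3' pseudo-domain VI.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    minlen = 30 if kind == "group_III" else 200
    if kind not in ("group_II", "group_III"):
        raise ValueError(f"unknown intron kind {kind!r}")
    if length < minlen:
        raise ValueError(f"{kind} intron must be >= {minlen} nt")

    if kind == "group_III":
        start = "".join([
            str(rng.choice(_DNA)), "T", str(rng.choice(_DNA)),
            str(rng.choice(_DNA)), "G",
        ])
        p_interior = np.array([
            (1 - u_fraction) * 0.45, (1 - u_fraction) * 0.275,
            (1 - u_fraction) * 0.275, u_fraction,
        ])
    else:
        start = "GTGCG"
        p_interior = np.array([0.3, 0.2, 0.2, 0.3])

    stem = _rand_seq(rng, 6, np.full(4, 0.25))
    rc = stem.translate(_COMPLEMENT)[::-1]  # a'b'c'...f' pair partners
    loop = _rand_seq(rng, 4, np.full(4, 0.25))
    tail = _rand_seq(rng, 4, np.full(4, 0.25))
    # layout: abcdef loop f'e'd' A* c'b'a' tail  (rc = f'e'd'c'b'a')
    domain = stem + loop + rc[:3] + "A" + rc[3:] + tail
    interior = _rand_seq(rng, length - len(start) - len(domain), p_interior)
    return start + interior + domain


def _label_branches(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.branch_label = node.taxon.label
        elif node.label:
            node.branch_label = node.label
        else:
            node.branch_label = f"node{k}"
            k += 1


def simulate_clade(cfg: SimulationConfig
                   ) -> tuple[dict[str, AnnotatedGenome], SimulationTruth]:
    """Simulate intron gain/loss/nesting on a tree and assemble genomes."""
    rng = np.random.default_rng(cfg.seed)
    tree = load_tree(cfg.tree)
    _label_branches(tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]

    gene_names = [g for g, _ in cfg.genes]
    gene_codons = dict(cfg.genes)
    # shared ancestral exon sequence per gene (stop-free interior not needed:
    # translations are only used as alignment rows)
    gene_seq = {
        g: _rand_seq(rng, 3 * n) for g, n in cfg.genes
    }

    sites: dict[str, SiteTruth] = {}
    seqs: dict[str, str] = {}  # site_key -> intron sequence (with nestings)
    occupied: set[tuple[str, int, int]] = set()
    counter = 0

    def new_site(branch: str) -> Optional[SiteTruth]:
        nonlocal counter
        for _ in range(50):  # rejection-sample an unoccupied position
            gene = gene_names[rng.integers(len(gene_names))]
            codon = int(rng.integers(1, gene_codons[gene] - 1))
            phase = int(rng.integers(3))
            if (gene, codon, phase) in occupied:
                continue
            occupied.add((gene, codon, phase))
            counter += 1
            key = f"s{counter:03d}"
            kind = ("group_III"
                    if rng.random() < cfg.group3_fraction else "group_II")
            lo, hi = (cfg.group3_len if kind == "group_III" else cfg.group2_len)
            length = int(rng.integers(lo, hi + 1))
            seqs[key] = generate_intron_sequence(kind, length, rng)
            return SiteTruth(site_key=key, gene=gene, codon=codon,
                             phase=phase, gain_branch=branch)
        return None

    def walk(node, carried: dict) -> None:
        """carried: site_key -> (intron sequence, internal spans) on this
        lineage; spans are (start, end) in current intron coordinates."""
        label = node.branch_label
        here = {k: (s, list(sp)) for k, (s, sp) in carried.items()}
        if node.parent_node is not None:  # root node has no branch above
            # losses
            for key in list(here):
                if rng.random() < cfg.loss_prob:
                    del here[key]
                    sites[key].loss_branches.append(label)
            # twintron nesting events
            for key in list(here):
                if rng.random() < cfg.nesting_prob:
                    internal = generate_intron_sequence(
                        "group_III", int(rng.integers(*cfg.group3_len)), rng)
                    host, spans = here[key]
                    pos = int(rng.integers(10, len(host) - 10))
                    ilen = len(internal)
                    new_spans = []
                    for a, b in spans:
                        if a >= pos:  # downstream internal shifts
                            new_spans.append((a + ilen, b + ilen))
                        elif a < pos < b:  # insertion lands inside it
                            new_spans.append((a, b + ilen))
                        else:
                            new_spans.append((a, b))
                    new_spans.append((pos, pos + ilen))
                    here[key] = (host[:pos] + internal + host[pos:], new_spans)
                    sites[key].nestings.append(label)
            # gains
            n_new = rng.poisson(cfg.intensity_for(label))
            for _ in range(n_new):
                st = new_site(label)
                if st is not None:
                    sites[st.site_key] = st
                    here[st.site_key] = (seqs[st.site_key], [])
        if node.is_leaf():
            for key in here:
                sites[key].present_in.add(label)
            leaf_payload[label] = here
        else:
            for ch in node.child_nodes():
                walk(ch, here)

    leaf_payload: dict[str, dict] = {}
    walk(tree.seed_node, {})

    genomes = {
        tag: _assemble_genome(tag, cfg, gene_seq, sites, leaf_payload[tag], rng)
        for tag in leaves
    }
    truth = SimulationTruth(
        sites=sorted(sites.values(), key=lambda s: s.site_key),
        species=leaves,
    )
    return genomes, truth


def _assemble_genome(tag: str, cfg: SimulationConfig, gene_seq: dict,
                     sites: dict, payload: dict[str, str],
                     rng: np.random.Generator) -> AnnotatedGenome:
    by_gene: dict[str, list] = {}
    for key, (iseq, spans) in payload.items():
        st = sites[key]
        by_gene.setdefault(st.gene, []).append(
            (st.codon * 3 + st.phase, iseq, spans))

    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i, (gname, _) in enumerate(cfg.genes):
        spacer = _rand_seq(rng, int(rng.integers(*cfg.spacer_len)))
        parts.append(spacer)
        pos += len(spacer)
        cds = gene_seq[gname]
        inserts = sorted(by_gene.get(gname, []))
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            exons, introns, cursor, prev = [], [], pos, 0
            for off, iseq, spans in inserts:
                exons.append((cursor, cursor + (off - prev)))
                cursor += off - prev
                introns.append((cursor, cursor + len(iseq), iseq, spans))
                cursor += len(iseq)
                prev = off
            exons.append((cursor, cursor + len(cds) - prev))
            cursor += len(cds) - prev
            body = _splice_body(cds, inserts)
        else:
            # write the reverse complement; an insertion at transcript
            # offset `off` sits at genomic offset (L_t - off) from the start
            body_t = _splice_body(cds, inserts)
            body = body_t.translate(_COMPLEMENT)[::-1]
            L = len(body)
            cuts = []  # genomic (start, end, seq, spans) of introns
            t_cursor = 0
            prev = 0
            for off, iseq, spans in inserts:
                t_cursor += off - prev
                g_end = pos + (L - t_cursor)
                cuts.append((g_end - len(iseq), g_end, iseq, spans))
                t_cursor += len(iseq)
                prev = off
            cuts.sort()
            exons, introns = [], []
            cursor = pos
            for cs, ce, iseq, spans in cuts:
                exons.append((cursor, cs))
                introns.append((cs, ce, iseq, spans))
                cursor = ce
            exons.append((cursor, pos + L))
            cursor = pos + L
        parts.append(body)
        pos += len(body)
        gene = GeneModel(name=gname, kind="protein", strand=strand,
                         exons=[e for e in exons if e[1] > e[0]])
        from .annotation_io import _attach_nested

        for s, e, iseq, spans in introns:
            top = IntronRecord(host_gene=gname, ordinal=0, interval=(s, e),
                               sequence=iseq)
            children = []
            for a, b in spans:
                child_iv = (s + a, s + b) if strand == "+" else (e - b, e - a)
                children.append(
                    IntronRecord(host_gene=gname, ordinal=0,
                                 interval=child_iv, sequence=iseq[a:b])
                )
            if children:
                _attach_nested([top], children)
            gene.introns.append(top)
        genes.append(gene)
    tail = _rand_seq(rng, int(rng.integers(*cfg.spacer_len)))
    parts.append(tail)
    genome = AnnotatedGenome(
        id=tag, species_tag=tag, sequence="".join(parts), genes=genes
    )
    from .annotation_io import _assign_ordinals

    _assign_ordinals(genome)
    return genome


def _splice_body(cds: str, inserts) -> str:
    out, prev = [], 0
    for off, iseq, *_ in sorted(inserts):
        out.append(cds[prev:off])
        out.append(iseq)
        prev = off
    out.append(cds[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# published-composition fixtures


@dataclass
class TwintronCohort:
    """Candidate twintron sites with known construction."""

    entries: list  # (site_id, target_sequence, TwintronReference, built_as)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_DNA[_DNA != out[i]]))
    return "".join(out)


def build_twintron_cohort(seed: int = 0, divergence: float = 0.10
                          ) -> TwintronCohort:
    """The 12-candidate-site cohort mirroring the published composition:
    4 sites carrying the external and every internal intron (complete), 2
    carrying the external and exactly one internal (intermediate stage), 6
    carrying the external only. Targets diverge from the reference by point
    substitutions at ``divergence``."""
    rng = np.random.default_rng(seed)
    plans = (
        [("complete", 1)] * 4
        + [("partial", 2), ("partial", 3)]
        + [("external_only", 1)] * 6
    )
    entries = []
    for i, (built_as, n_internals) in enumerate(plans, 1):
        ext_len = int(rng.integers(250, 450))
        external = generate_intron_sequence("group_II", ext_len, rng)
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(30, ext_len - 30), size=n_internals, replace=False)
        )
        internals = tuple(
            (generate_intron_sequence(
                "group_III", int(rng.integers(70, 130)), rng), pos)
            for pos in positions
        )
        ref = TwintronReference(
            site_id=f"site{i:02d}", external=external, internals=internals,
            groups=("GII",) + ("GIII",) * n_internals,
        )
        if built_as == "complete":
            keep = range(n_internals)
        elif built_as == "partial":
            keep = [n_internals - 1]  # the last internal, as observed in vivo
        else:
            keep = []
        target = _mutate(ref.with_internals(keep), divergence, rng)
        entries.append((ref.site_id, target, ref, built_as))
    return TwintronCohort(entries=entries)


def build_paper_fixture(seed: int = 0
                        ) -> tuple[list[SiteGroup], TwintronCohort]:
    """The shipped site-catalog transcription plus the synthetic
    12-candidate twintron cohort."""
    return load_site_fixture(), build_twintron_cohort(seed)
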