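"""Projection and cross-species clustering of intron insertion sites.

An insertion site is identified by the alignment column of the interrupted
residue plus the codon phase of the insertion point (0 = exactly between
codons, assigned to the following residue's column). Two introns are
cognate iff they fall at the same (gene, column, phase): insertions within
the same amino acid but at different positions in the codon are distinct
sites. Sites can be flagged ambiguous, in which case they are kept distinct
from everything (used for weakly conserved genes where column homology is
doubtful).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignment import MultipleAlignment
from .annotation_io import IntronRecord

__all__ = [
    "AlignedSite",
    "SiteGroup",
    "ProjectionError",
    "parse_site_id",
    "project_site",
    "cluster_cognate_sites",
    "site_catalog",
    "load_site_fixture",
]

_SITE_ID = re.compile(r"^(?P<gene>[^.]+)\.(?P<tag>[^.]+)\.(?P<ord>\d+)$")


class ProjectionError(ValueError):
    """A site cannot be placed in alignment coordinates."""


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    m = _SITE_ID.match(site_id)
    if not m:
        raise ValueError(f"malformed site id {site_id!r}")
    return m["gene"], m["tag"], int(m["ord"])


@dataclass(frozen=True)
class AlignedSite:
    """An intron insertion site projected onto a per-gene protein alignment."""

    site_id: str  # "gene.SpeciesTag.ordinal"
    gene: str
    species_tag: str
    column: int  # alignment column of the interrupted residue
    phase: int  # {0,1,2}

    def __post_init__(self):
        g, t, _ = parse_site_id(self.site_id)
        if (g, t) != (self.gene, self.species_tag):
            raise ValueError(f"site_id {self.site_id} inconsistent with fields")


@dataclass
class SiteGroup:
    """A cross-species cluster of cognate insertion sites (<=1 per species)."""

    gene: str
    members: tuple[AlignedSite, ...]
    twintron_flags: dict = field(default_factory=dict)  # site_id -> bool
    ambiguous: bool = False
    note: str = ""

    @property
    def species(self) -> frozenset[str]:
        return frozenset(m.species_tag for m in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def twintron(self) -> bool:
        """Any member reported to display a twintron."""
        return any(self.twintron_flags.values())

    def member_for(self, tag: str) -> Optional[AlignedSite]:
        for m in self.members:
            if m.species_tag == tag:
                return m
        return None


def project_site(intron: IntronRecord, msa: MultipleAlignment,
                 species_tag: str, row: Optional[str] = None) -> AlignedSite:
    """Project an intron insertion point to (alignment column, phase).

    The interrupted residue is ``cds_offset // 3``; for phase-0 insertions
    this is the residue following the insertion point.
    """
    if intron.phase is None or intron.cds_offset is None:
        raise ProjectionError(
            f"{intron.site_id}: phase undefined (non-protein host?)"
        )
    row = row if row is not None else species_tag
    ridx = msa.row_index(row) if isinstance(row, str) else row
    residue = intron.cds_offset // 3
    n_res = len(msa.ungapped(ridx))
    if residue >= n_res:
        raise ProjectionError(
            f"{intron.site_id}: residue {residue} beyond row of {n_res} "
            "residues (terminal gap)"
        )
    column = msa.column_of(ridx, residue)
    return AlignedSite(
        site_id=f"{intron.host_gene}.{species_tag}.{intron.ordinal}",
        gene=intron.host_gene, species_tag=species_tag,
        column=column, phase=intron.phase,
    )


def cluster_cognate_sites(
    sites: Iterable[AlignedSite],
    keep_distinct: Iterable[str] = (),
    twintron_flags: Optional[Mapping[str, bool]] = None,
) -> list[SiteGroup]:
    """Group sites that share (gene, column, phase).

    ``keep_distinct`` lists site ids whose column homology is considered
    ambiguous; each forms its own group flagged ``ambiguous``. Two sites of
    the same species at one (gene, column, phase) indicate a duplicate
    annotation and raise.
    """
    keep_distinct = set(keep_distinct)
    flags = dict(twintron_flags or {})
    buckets: dict[tuple, list[AlignedSite]] = {}
    singletons: list[AlignedSite] = []
    for s in sorted(sites, key=lambda s: s.site_id):
        if s.site_id in keep_distinct:
            singletons.append(s)
        else:
            buckets.setdefault((s.gene, s.column, s.phase), []).append(s)

    groups: list[SiteGroup] = []
    for (gene, col, phase), members in buckets.items():
        tags = [m.species_tag for m in members]
        if len(tags) != len(set(tags)):
            dup = next(t for t in tags if tags.count(t) > 1)
            raise ValueError(
                f"duplicate annotation: two {dup} sites in {gene} at "
                f"column {col} phase {phase}"
            )
        groups.append(
            SiteGroup(
                gene=gene, members=tuple(members),
                twintron_flags={
                    m.site_id: flags.get(m.site_id, False) for m in members
                },
            )
        )
    for s in singletons:
        groups.append(
            SiteGroup(
                gene=s.gene, members=(s,),
                twintron_flags={s.site_id: flags.get(s.site_id, False)},
                ambiguous=True,
            )
        )
    groups.sort(key=lambda g: (g.gene, min(m.column for m in g.members),
                               min(m.phase for m in g.members)))
    return groups


def site_catalog(groups: Sequence[SiteGroup], focal_species: str
                 ) -> tuple[pd.DataFrame, dict]:
    """Per-site catalog for one focal species plus summary counts.

    Returns a table with one row per focal-species site (partners listed),
    and a summary dict with keys ``total``, ``shared``, ``unique`` and
    ``twintron_shared`` (groups whose members are reported to display
    twintrons in a partner genome).
    """
    if not any(g.member_for(focal_species) for g in groups):
        raise ValueError(f"unknown focal species {focal_species!r}")
    rows = []
    n_shared = n_unique = n_twin = 0
    for g in groups:
        me = g.member_for(focal_species)
        if me is None:
            continue
        partners = sorted(
            m.site_id for m in g.members if m.species_tag != focal_species
        )
        shared = len(partners) > 0
        n_shared += shared
        n_unique += not shared
        n_twin += g.twintron
        rows.append(
            {
                "site_id": me.site_id,
                "gene": g.gene,
                "column": me.column,
                "phase": me.phase,
                "partners": ",".join(partners),
                "twintron_flag": g.twintron,
                "ambiguous": g.ambiguous,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "total": len(rows),
        "shared": n_shared,
        "unique": n_unique,
        "twintron_shared": n_twin,
    }
    return df, summary


# ---------------------------------------------------------------------------
# published-catalog fixture


def _fixture_path(name: str):
    from importlib.resources import files

    return files("plastintron.data") / name


def load_site_fixture(shared_path=None, unique_path=None) -> list[SiteGroup]:
    """Machine-readable transcription of the published shared/unique site
    catalogs as SiteGroups.

    Alignment columns are not published, so each catalog row is assigned its
    own synthetic column; phases are unknowable from the tables and set to 0.
    The twintron flag marks rows whose partner introns are reported to
    display twintrons; rows noted ambiguous stay distinct.
    """
    shared_path = shared_path or _fixture_path("table2_shared_sites.tsv")
    unique_path = unique_path or _fixture_path("table3_unique_sites.tsv")
    shared = pd.read_csv(str(shared_path), sep="\t").fillna("")
    unique = pd.read_csv(str(unique_path), sep="\t").fillna("")

    groups: list[SiteGroup] = []
    col = 0
    for _, row in shared.iterrows():
        gene = row["gene"]
        members = []
        for tok in str(row["members"]).split(","):
            tag, ordinal = tok.strip().split(".")
            members.append(
                AlignedSite(
                    site_id=f"{gene}.{tag}.{ordinal}", gene=gene,
                    species_tag=tag, column=col, phase=0,
                )
            )
        twin = bool(int(row["egra_twintron"]))
        groups.append(
            SiteGroup(
                gene=gene, members=tuple(members),
                twintron_flags={m.site_id: twin for m in members},
                note=str(row.get("note", "")),
            )
        )
        col += 10
    for _, row in unique.iterrows():
        gene, tag, ordinal = parse_site_id(row["site_id"])
        site = AlignedSite(
            site_id=row["site_id"], gene=gene, species_tag=tag,
            column=col, phase=0,
        )
        note = str(row.get("note", ""))
        groups.append(
            SiteGroup(
                gene=gene, members=(site,),
                twintron_flags={site.site_id: False},
                ambiguous=note.startswith("ambiguous"),
                note=note,
            )
        )
        col += 10
    return groups
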