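"""Protein and nucleotide alignment utilities.

Pairwise alignment is affine-gap Needleman-Wunsch (Bio.Align.PairwiseAligner
with a BLOSUM62 default for proteins); a gap of length L costs
``gap_open + (L - 1) * gap_extend``. The small multiple aligner is a
center-star progressive method ("once a gap, always a gap"), adequate for
the near-identical ortholog sets used to map intron insertion sites; true
externally computed alignments can be imported and take precedence.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

__all__ = [
    "ScoringScheme",
    "NucleotideScheme",
    "MultipleAlignment",
    "global_align",
    "semi_global_align",
    "star_msa",
    "import_alignment",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap protein scoring (substitution matrix by name)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load(self.matrix)
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass(frozen=True)
class NucleotideScheme:
    """Match/mismatch nucleotide scoring with affine gaps.

    Defaults suit intron-component comparison, where real length differences
    are whole-intron-sized indels: opening a gap is expensive but extending
    is nearly free (one absent 100-nt component costs one opening), and a
    mismatch outweighs a match so that pairing through unrelated AT-rich
    sequence scores worse than gapping it out.
    """

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = 16.0
    gap_extend: float = 0.5

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a


class MultipleAlignment:
    """Equal-length aligned rows with residue<->column coordinate maps."""

    GAP = "-"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in rows}) > 1:
            raise ValueError("ragged alignment rows")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self._res2col: list[list[int]] = []
        self._col2res: list[list[Optional[int]]] = []
        for row in self.rows:
            r2c, c2r, k = [], [], 0
            for col, ch in enumerate(row):
                if ch == self.GAP:
                    c2r.append(None)
                else:
                    r2c.append(col)
                    c2r.append(k)
                    k += 1
            self._res2col.append(r2c)
            self._col2res.append(c2r)

    # -- basic shape -------------------------------------------------------
    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row_index(self, rid: str) -> int:
        return self.ids.index(rid)

    def ungapped(self, row) -> str:
        i = row if isinstance(row, int) else self.row_index(row)
        return self.rows[i].replace(self.GAP, "")

    # -- coordinate maps ---------------------------------------------------
    def column_of(self, row, residue_index: int) -> int:
        """Alignment column holding this (0-based) residue of a row."""
        i = row if isinstance(row, int) else self.row_index(row)
        return self._res2col[i][residue_index]

    def residue_at(self, row, column: int) -> Optional[int]:
        """Residue index at a column of a row, or None on a gap."""
        i = row if isinstance(row, int) else self.row_index(row)
        return self._col2res[i][column]

    # -- I/O ---------------------------------------------------------------
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i: i + 60] + "\n")


def _check_protein(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - PROTEIN_ALPHABET
    if not s:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"illegal residue symbols: {sorted(bad)}")
    return s


def _first_alignment(aln_iter):
    # PairwiseAligner enumerates co-optimal alignments deterministically;
    # the first is our canonical traceback.
    return next(iter(aln_iter))


def _rows_from_biopython(aln) -> tuple[str, str]:
    text = str(aln).splitlines()
    # Alignment str format: target / match / query triplets; use indices API
    a, b = aln[0], aln[1]
    return str(a), str(b)


def global_align(a: str, b: str,
                 scheme: Optional[ScoringScheme] = None
                 ) -> tuple[MultipleAlignment, float]:
    """Optimal global alignment of two protein sequences; returns the
    pairwise alignment and its score."""
    scheme = scheme or ScoringScheme()
    a, b = _check_protein(a), _check_protein(b)
    res = scheme.aligner().align(a, b)
    best = _first_alignment(res)
    ra, rb = _rows_from_biopython(best)
    return MultipleAlignment(["seq1", "seq2"], [ra, rb]), float(res.score)


def semi_global_align(ref: str, target: str,
                      scheme: Optional[NucleotideScheme] = None):
    """Glocal nucleotide alignment: the reference aligns in full, the target
    flanks are free. Returns (ref_row, target_row, score)."""
    if not ref or not target:
        raise ValueError("empty sequence")
    scheme = scheme or NucleotideScheme()
    al = scheme.aligner()
    # gaps appended to the reference (query) ends are free: the reference may
    # land anywhere inside the target
    try:
        al.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        al.query_end_gap_score = 0.0
    res = al.align(target.upper().replace("U", "T"),
                   ref.upper().replace("U", "T"))
    best = _first_alignment(res)
    t_row, r_row = _rows_from_biopython(best)
    return r_row, t_row, float(res.score)


def _merge_center(master: str, new_center: str) -> tuple[list[int], list[int]]:
    """Column maps merging two gapped versions of the same center sequence.

    Returns (cols_from_master, cols_from_new) mapping each merged column to a
    source column or -1 where that source needs a fresh gap.
    """
    i = j = 0
    m_map, n_map = [], []
    while i < len(master) or j < len(new_center):
        mi = master[i] if i < len(master) else None
        nj = new_center[j] if j < len(new_center) else None
        if mi is not None and nj is not None and (mi != "-") == (nj != "-"):
            m_map.append(i); n_map.append(j); i += 1; j += 1
        elif mi == "-":
            m_map.append(i); n_map.append(-1); i += 1
        elif nj == "-":
            m_map.append(-1); n_map.append(j); j += 1
        elif mi is None:
            m_map.append(-1); n_map.append(j); j += 1
        else:
            m_map.append(i); n_map.append(-1); i += 1
    return m_map, n_map


def star_msa(seqs: Sequence[str], ids: Optional[Sequence[str]] = None,
             scheme: Optional[ScoringScheme] = None) -> MultipleAlignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing its summed pairwise score to all
    others; every other sequence is merged through its pairwise alignment to
    the center with "once a gap, always a gap" propagation.
    """
    if len(seqs) < 2:
        raise ValueError("star_msa needs at least 2 sequences")
    scheme = scheme or ScoringScheme()
    ids = list(ids) if ids is not None else [f"seq{i+1}" for i in range(len(seqs))]
    seqs = [_check_protein(s) for s in seqs]
    if len(seqs) == 2:
        aln, _ = global_align(seqs[0], seqs[1], scheme)
        return MultipleAlignment(ids, aln.rows)

    n = len(seqs)
    pair: dict[tuple[int, int], tuple[MultipleAlignment, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair[(i, j)] = global_align(seqs[i], seqs[j], scheme)
    totals = [
        sum(pair[tuple(sorted((i, j)))][1] for j in range(n) if j != i)
        for i in range(n)
    ]
    center = max(range(n), key=lambda i: (totals[i], -i))

    others = [i for i in range(n) if i != center]
    master = seqs[center]
    rows: list[str] = []  # peripheral rows, in `others` order
    for k, o in enumerate(others):
        i, j = sorted((center, o))
        aln, _ = pair[(i, j)]
        c_row = aln.rows[0 if center == i else 1]
        o_row = aln.rows[1 if center == i else 0]
        m_map, n_map = _merge_center(master, c_row)
        master = "".join(
            master[m] if m >= 0 else c_row[nn]
            for m, nn in zip(m_map, n_map)
        )
        rows = [
            "".join(r[m] if m >= 0 else "-" for m in m_map) for r in rows
        ]
        rows.append("".join(o_row[nn] if nn >= 0 else "-" for nn in n_map))

    all_rows = [master] + rows
    order = [center] + others
    final = [all_rows[order.index(i)] for i in range(n)]
    return MultipleAlignment(ids, final)


def import_alignment(path) -> MultipleAlignment:
    """Import an externally produced aligned FASTA (e.g. MAFFT output)."""
    path = Path(path)
    aln = AlignIO.read(str(path), "fasta")
    return MultipleAlignment([r.id for r in aln], [str(r.seq) for r in aln])
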