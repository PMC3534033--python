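"""Group III intron consensus scanning.

Euglenid plastid group III introns are small, U-rich, degenerate group II
introns retaining two recognizable landmarks: a 5'-NUNNG start consensus and
a 3'-terminal pseudo-domain VI — a six-pair stem interrupted by a loop, with
a bulged adenosine (the branch point of the lariat-forming nucleophilic
attack) between the two 3' stem segments, followed by a short tail ending at
the intron terminus:

    5'- a b c d e f (loop 3-8) f' e' d'  A*  c' b' a' (tail 4) -3'

The scanner enumerates every placement of this layout inside a 3' search
window; stem positions must pair (Watson-Crick, optionally G.U) up to a
mismatch budget. T and U are equivalent throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .annotation_io import IntronRecord

__all__ = [
    "MotifParams",
    "DomainVIHit",
    "IntronClassification",
    "scan_5prime",
    "find_domain_vi",
    "classify_intron",
    "scan_report",
]

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class MotifParams:
    """Tunable pseudo-domain VI scan parameters."""

    loop_min: int = 3
    loop_max: int = 8
    tail_min: int = 4
    tail_max: int = 4
    allow_gu: bool = True
    max_mismatch: int = 0
    search_window: int = 40  # nt from the 3' end the motif may start in

    def __post_init__(self):
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min > loop_max")
        if self.tail_min < 0 or self.tail_min > self.tail_max:
            raise ValueError("bad tail range")


@dataclass(frozen=True)
class DomainVIHit:
    """One placement of the stem-bulge-tail layout.

    ``span`` = 13 + loop_len + tail_len (six 5' stem bases, loop, three 3'
    stem bases, the bulged A, three more stem bases, tail).
    """

    stem5_start: int  # index of base a
    loop_len: int
    bulge_index: int  # index of the bulged adenosine
    tail_len: int
    pairings: tuple  # ((base5, base3, kind) * 6), kind in {"WC","GU","x"}
    mismatches: int

    @property
    def span(self) -> int:
        return 13 + self.loop_len + self.tail_len


@dataclass(frozen=True)
class IntronClassification:
    label: str  # group_II | group_III | unclassified
    length: int
    u_fraction: float  # diagnostic only
    five_prime_match: bool
    five_prime_mer: str
    n_domain_vi_hits: int


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def scan_5prime(seq: str) -> tuple[bool, str]:
    """True iff the intron starts N-U-N-N-G (positions 2 and 5, 1-based)."""
    s = _rna(seq)
    if len(s) < 5:
        raise ValueError("sequence shorter than 5 nt")
    mer = s[:5]
    return (mer[1] == "U" and mer[4] == "G"), mer


def _pair_kind(x: str, y: str, allow_gu: bool) -> str:
    if (x, y) in WATSON_CRICK:
        return "WC"
    if allow_gu and (x, y) in WOBBLE:
        return "GU"
    return "x"


def find_domain_vi(seq: str, params: Optional[MotifParams] = None
                   ) -> list[DomainVIHit]:
    """All pseudo-domain VI placements ending at the intron 3' terminus.

    Hits are sorted best first: fewest stem mismatches, then shortest loop,
    then most 3' placement.
    """
    p = params or MotifParams()
    s = _rna(seq)
    n = len(s)
    hits: list[DomainVIHit] = []
    for tail in range(p.tail_min, p.tail_max + 1):
        for loop in range(p.loop_min, p.loop_max + 1):
            span = 13 + loop + tail
            start = n - span
            if start < 0 or span > p.search_window:
                continue
            if s[start + 9 + loop] != "A":  # the bulged adenosine
                continue
            # pairs: a..f (start..start+5) with a'..f' read 3'->5'
            prime = {
                5: start + 6 + loop,   # f'
                4: start + 7 + loop,   # e'
                3: start + 8 + loop,   # d'
                2: start + 10 + loop,  # c'
                1: start + 11 + loop,  # b'
                0: start + 12 + loop,  # a'
            }
            pairings = tuple(
                (s[start + k], s[prime[k]],
                 _pair_kind(s[start + k], s[prime[k]], p.allow_gu))
                for k in range(6)
            )
            mism = sum(1 for _, _, kind in pairings if kind == "x")
            if mism <= p.max_mismatch:
                hits.append(
                    DomainVIHit(
                        stem5_start=start, loop_len=loop,
                        bulge_index=start + 9 + loop, tail_len=tail,
                        pairings=pairings, mismatches=mism,
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.loop_len, -h.stem5_start))
    return hits


def classify_intron(intron, params: Optional[MotifParams] = None,
                    max_g3_len: int = 150) -> IntronClassification:
    """Classify an intron as group II / group III / unclassified.

    group III: 5' consensus matches, a pseudo-domain VI is found, and the
    intron is short (<= ``max_g3_len``, a configurable operational ceiling —
    group III introns are small but no hard published bound exists).
    group II: a pseudo-domain VI is found in a long intron. U content is
    reported as a diagnostic, never a criterion.
    """
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    if not seq:
        raise ValueError("empty intron sequence")
    s = _rna(seq)
    five_ok, mer = scan_5prime(s) if len(s) >= 5 else (False, s)
    hits = find_domain_vi(s, params) if len(s) >= 13 + (params or MotifParams()).loop_min else []
    if hits and len(s) <= max_g3_len and five_ok:
        label = "group_III"
    elif hits and len(s) > max_g3_len:
        label = "group_II"
    else:
        label = "unclassified"
    return IntronClassification(
        label=label, length=len(s),
        u_fraction=s.count("U") / len(s),
        five_prime_match=five_ok, five_prime_mer=mer,
        n_domain_vi_hits=len(hits),
    )


def relax(params: MotifParams, **changes) -> MotifParams:
    """Convenience for widening scan parameters."""
    return replace(params, **changes)


def scan_report(introns, params: Optional[MotifParams] = None,
                max_g3_len: int = 150) -> pd.DataFrame:
    """Tabular classification report for a collection of introns.

    ``introns`` is an iterable of (id, sequence) pairs or IntronRecords.
    """
    rows = []
    for item in introns:
        if isinstance(item, IntronRecord):
            iid, seq = item.site_id, item.sequence
        else:
            iid, seq = item
        c = classify_intron(seq, params, max_g3_len)
        rows.append(
            {
                "intron_id": iid, "length": c.length,
                "u_fraction": round(c.u_fraction, 3),
                "five_prime_mer": c.five_prime_mer,
                "five_prime_match": c.five_prime_match,
                "n_domain_vi_hits": c.n_domain_vi_hits,
                "class": c.label,
                "max_g3_len": max_g3_len,
            }
        )
    return pd.DataFrame(rows)
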