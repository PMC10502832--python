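"""Per-gene regulatory features: CPE/PAS motif scanning on 3'UTRs, papCPE
calling, gene-set tagging, and RIP-seq replicate consensus.

The scanner works on the sense strand of the mRNA 3'UTR in DNA alphabet
(T, not U). Default patterns follow the CPE consensus literature:
CPE = {TTTTAT, TTTTAAT}, PAS = {AATAAA, ATTAAA}; both are configurable
IUPAC strings. A papCPE is a CPE lying within ``papcpe_window`` nucleotides
of a PAS, where the gap counts nucleotides strictly between the two
matches (touching or overlapping matches have gap 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import GeneSet, ValidationError

__all__ = [
    "MotifHit",
    "UTRAnnotation",
    "DEFAULT_CPE_PATTERNS",
    "DEFAULT_PAS_PATTERNS",
    "scan_motifs",
    "call_papcpe",
    "annotate_utrs",
    "tag_genes",
    "rip_consensus",
    "hits_to_bed",
]

DEFAULT_CPE_PATTERNS = ("TTTTAT", "TTTTAAT")
DEFAULT_PAS_PATTERNS = ("AATAAA", "ATTAAA")

#: IUPAC nucleotide codes -> concrete base sets. N in the *sequence* never
#: matches anything; N in a *pattern* matches any concrete base.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, 0-based half-open within the 3'UTR."""

    gene_id: str
    kind: str  # "CPE" or "PAS"
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad hit coordinates [{self.start},{self.end})")
        if len(self.matched_text) != self.end - self.start:
            raise ValidationError("matched_text length must equal end - start")


@dataclass(frozen=True)
class UTRAnnotation:
    """Summary of CPE/PAS content for one gene's 3'UTR."""

    gene_id: str
    cpe_count: int
    pas_count: int
    has_cpe: bool
    has_papcpe: bool
    min_cpe_pas_gap: int | None


def _compile(pattern: str) -> "re.Pattern[str]":
    """IUPAC pattern -> overlapping-match regex.

    A lookahead capture yields every (including overlapping) occurrence.
    Classes contain concrete bases only, so N in the sequence matches no
    pattern position.
    """
    if not pattern:
        raise ValidationError("empty pattern string")
    parts = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise ValidationError(f"invalid IUPAC code {c!r} in {pattern!r}")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    gene_id: str,
    utr3_sequence: str,
    cpe_patterns: Sequence[str] = DEFAULT_CPE_PATTERNS,
    pas_patterns: Sequence[str] = DEFAULT_PAS_PATTERNS,
) -> list[MotifHit]:
    """All (including overlapping) CPE/PAS occurrences on the sense strand.

    Hits are sorted by start position, then kind, then end. An N in the
    sequence matches no pattern position.
    """
    if not cpe_patterns and not pas_patterns:
        raise ValidationError("empty pattern set")
    seq = utr3_sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"{gene_id}: sequence outside ACGTN: {sorted(bad)}")
    hits: list[MotifHit] = []
    for kind, patterns in (("CPE", cpe_patterns), ("PAS", pas_patterns)):
        for pattern in patterns:
            rx = _compile(pattern)
            for m in rx.finditer(seq):
                text = m.group(1)
                hits.append(MotifHit(gene_id, kind, m.start(), m.start() + len(text), text))
    hits.sort(key=lambda h: (h.start, h.kind, h.end))
    return hits


def call_papcpe(hits: Sequence[MotifHit], window: int = 100) -> UTRAnnotation:
    """Summarize one gene's hits into CPE/PAS counts and the papCPE flag.

    The gap between a CPE and a PAS is ``max(0, larger start - smaller
    end)``: nucleotides strictly between the matches, 0 if they touch or
    overlap. has_papcpe is true iff the minimum gap over all CPE-PAS pairs
    is <= window. Enlarging the window can only turn the flag on, never off.
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValidationError(f"hits from multiple genes: {sorted(genes)}")
    gene_id = hits[0].gene_id if hits else ""
    cpes = [h for h in hits if h.kind == "CPE"]
    pases = [h for h in hits if h.kind == "PAS"]
    min_gap: int | None = None
    if cpes and pases:
        min_gap = min(
            max(0, max(c.start, p.start) - min(c.end, p.end))
            for c in cpes
            for p in pases
        )
    return UTRAnnotation(
        gene_id=gene_id,
        cpe_count=len(cpes),
        pas_count=len(pases),
        has_cpe=bool(cpes),
        has_papcpe=min_gap is not None and min_gap <= window,
        min_cpe_pas_gap=min_gap,
    )


def annotate_utrs(
    sequences: Mapping[str, str],
    window: int = 100,
    cpe_patterns: Sequence[str] = DEFAULT_CPE_PATTERNS,
    pas_patterns: Sequence[str] = DEFAULT_PAS_PATTERNS,
) -> dict[str, UTRAnnotation]:
    """Scan and summarize every 3'UTR in a gene -> sequence mapping."""
    out: dict[str, UTRAnnotation] = {}
    for gid, seq in sequences.items():
        hits = scan_motifs(gid, seq, cpe_patterns, pas_patterns)
        ann = call_papcpe(hits, window=window)
        # call_papcpe on an empty hit list has no gene id to carry
        out[gid] = ann if hits else UTRAnnotation(gid, 0, 0, False, False, None)
    return out


def tag_genes(
    universe: Iterable[str],
    m6a_set: GeneSet | None = None,
    cpe_annotations: Mapping[str, UTRAnnotation] | None = None,
    rip_set: GeneSet | None = None,
) -> pd.DataFrame:
    """Per-gene boolean feature table (m6a, cpe, papcpe, rip_target).

    Genes absent from an annotation source get False for that flag.
    A papCPE flag forces the CPE flag (a papCPE is a CPE).
    """
    genes = list(universe)
    cpe_annotations = cpe_annotations or {}

    def _papcpe(g: str) -> bool:
        ann = cpe_annotations.get(g)
        return bool(ann and ann.has_papcpe)

    def _cpe(g: str) -> bool:
        ann = cpe_annotations.get(g)
        return bool(ann and (ann.has_cpe or ann.has_papcpe))

    return pd.DataFrame(
        {
            "m6a": [m6a_set is not None and g in m6a_set for g in genes],
            "cpe": [_cpe(g) for g in genes],
            "papcpe": [_papcpe(g) for g in genes],
            "rip_target": [rip_set is not None and g in rip_set for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


def rip_consensus(
    replicate_sets: Sequence[GeneSet], min_support: int | None = None
) -> GeneSet:
    """Consensus target set across RIP-seq replicates.

    Default ``min_support`` is the number of replicates (strict
    intersection). Members are kept if they appear in at least
    ``min_support`` replicate sets.
    """
    if not replicate_sets:
        raise ValidationError("need at least one replicate set")
    n = len(replicate_sets)
    if min_support is None:
        min_support = n
    if not (1 <= min_support <= n):
        raise ValidationError(f"min_support {min_support} not in [1, {n}]")
    counts: dict[str, int] = {}
    for rs in replicate_sets:
        for g in rs.members:
            counts[g] = counts.get(g, 0) + 1
    members = sorted(g for g, c in counts.items() if c >= min_support)
    return GeneSet.from_iterable(f"rip_consensus_{min_support}of{n}", members)


def hits_to_bed(hits: Sequence[MotifHit]) -> str:
    """Render motif hits as BED6 text (0-based half-open, score 0, strand +)."""
    lines = [
        f"{h.gene_id}\t{h.start}\t{h.end}\t{h.kind}:{h.matched_text}\t0\t+"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
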