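"""Sequence fingerprints of [FeFe] hydrogenases.

Three short conserved motifs (P1, P2, P3) line the H-cluster cavity; in
the *Chlorella vulgaris* candidate the canonical P1 core TSCCPGW appears
as ASACPGW, which this module detects as a two-mismatch P1 hit with the
CPGW cysteine anchored.  The auxiliary [4Fe4S] F-cluster is bound by four
cysteines whose spacing is summarized as a CxnC-style pattern (e.g.
Cx50Cx2Cx2C for positions 21, 72, 75, 78).

Mismatch scoring is Hamming -- the fingerprints are short ungapped cores;
gapped alignment belongs to external aligners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import DomainMap

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Cores quoted for the H-cluster binding fingerprint.  P2/P3 extents are
#: configuration data (figure content, not asserted strings); users extend
#: this library from their own alignments.
DEFAULT_MOTIFS: dict[str, str] = {
    "P1": "TSCCPGW",      # canonical core; ASACPGW in Cvu
}


@dataclass(frozen=True)
class MotifDef:
    """A short ungapped consensus with a mismatch budget and exact anchors.

    Offsets into the consensus are 1-based, like every residue position in
    this package (anchor 4 of TSCCPGW is the cysteine of the CPGW block).
    """

    motif_id: str
    consensus: str
    max_mismatches: int = 0
    anchored_positions: frozenset[int] = frozenset()  # 1-based offsets

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        if any(p < 1 or p > len(self.consensus) for p in self.anchored_positions):
            raise ValueError("anchored positions must lie within the consensus")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int                     # 1-based position in the sequence
    matched: str
    mismatch_positions: tuple[int, ...]  # 1-based offsets into the consensus

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass(frozen=True)
class CysPattern:
    """Ordered cysteine positions and their spacer summary string."""

    positions: tuple[int, ...]
    spacers: tuple[int, ...]
    spacer_string: str


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-amino letters: {sorted(bad)}")
    return sequence


def scan_motifs(sequence: str, motifs: Sequence[MotifDef]) -> list[MotifHit]:
    """All windows within the mismatch budget, anchors matched exactly.

    Overlapping hits are allowed; the result is sorted by start position
    (then motif id).  ``X`` in the sequence always counts as a mismatch and
    never satisfies an anchor.  A sequence shorter than the consensus
    yields no hits.
    """
    sequence = _check_sequence(sequence)
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif.consensus)
        for start in range(len(sequence) - m + 1):
            window = sequence[start:start + m]
            mism = tuple(i + 1 for i, (a, b) in enumerate(zip(window, motif.consensus))
                         if a != b or a == "X")
            if len(mism) > motif.max_mismatches:
                continue
            if any(p in mism for p in motif.anchored_positions):
                continue
            hits.append(MotifHit(motif.motif_id, start + 1, window, mism))
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def find_cys_positions(sequence: str) -> list[int]:
    """1-based positions of every cysteine, ascending."""
    sequence = _check_sequence(sequence)
    return [i + 1 for i, c in enumerate(sequence) if c == "C"]


def detect_cys_pattern(positions: Sequence[int]) -> CysPattern:
    """Spacer pattern of ordered Cys positions, e.g. [21,72,75,78] -> Cx50Cx2Cx2C."""
    positions = tuple(int(p) for p in positions)
    if len(positions) < 2:
        raise ValueError("pattern undefined: need at least 2 Cys positions")
    if any(p <= 0 for p in positions):
        raise ValueError("positions must be positive (1-based)")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    spacers = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    spacer_string = "C" + "".join(f"x{s}C" for s in spacers)
    return CysPattern(positions, spacers, spacer_string)


def expand_cys_pattern(pattern: CysPattern) -> str:
    """Inverse of :func:`detect_cys_pattern` up to the spacer identities."""
    return "C" + "".join("x" * s + "C" for s in pattern.spacers)


@dataclass(frozen=True)
class SegmentConfig:
    """Offsets for heuristic domain segmentation around the P1 hit.

    The H-domain is taken to start ``p1_upstream_offset`` residues before
    the P1 hit and to end ``p1_downstream_offset`` residues after it; the
    defaults reproduce the hypothesized Cvu architecture (F 1-88,
    H 89-530, C-terminus 531-549) when P1 sits at position 223 of a
    549-residue sequence.
    """

    p1_upstream_offset: int = 134
    p1_downstream_offset: int = 307


def segment_domains(sequence: str,
                    hits: Sequence[MotifHit] = (),
                    f_cluster_cys: CysPattern | None = None,
                    boundaries: dict[str, tuple[int, int]] | None = None,
                    config: SegmentConfig = SegmentConfig()) -> DomainMap:
    """Three-part F / H / C-terminus segmentation.

    Explicit ``boundaries`` are authoritative (curated tables are the
    supported mode; the heuristic is a fallback).  In heuristic mode the
    F/H boundary is placed relative to the P1 hit per ``config``.
    """
    sequence = _check_sequence(sequence)
    n = len(sequence)
    if boundaries is not None:
        for label, (lo, hi) in boundaries.items():
            if lo < 1 or hi > n:
                raise ValueError(
                    f"domain {label!r}: interval {lo}-{hi} outside sequence 1-{n}")
        return DomainMap(boundaries)  # overlap validation inside DomainMap

    p1_hits = [h for h in hits if h.motif_id == "P1"]
    if not p1_hits:
        raise ValueError("cannot segment: no P1 hit and no explicit boundaries")
    p1 = min(p1_hits, key=lambda h: h.n_mismatches)
    h_start = max(1, p1.start - config.p1_upstream_offset)
    h_end = min(n, p1.start + config.p1_downstream_offset)
    ranges: dict[str, tuple[int, int]] = {}
    if h_start > 1:
        ranges["F"] = (1, h_start - 1)
    ranges["H"] = (h_start, h_end)
    if h_end < n:
        ranges["C"] = (h_end + 1, n)
    return DomainMap(ranges)
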