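"""Scan proteins for the bHLH-interaction consensus motif.

R2R3-MYB proteins that act in MYB-bHLH-WD40 (MBW) complexes carry the
bHLH-binding consensus [D/E]Lx2[R/K]x3Lx6Lx3R.  The scan is a pure
positional-pattern match over every 20-residue window: positions 1, 2,
5, 9, 16 and 20 of the window are constrained, the x positions match any
standard residue (including X); X never satisfies a constrained
position.  Overlapping occurrences are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import SequenceValidationError

#: Motif length in residues.
MOTIF_LEN = 20

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# [D/E] L x x [R/K] x x x L x x x x x x L x x x R  (20 positions)
_MOTIF_RE = re.compile(r"(?=([DE]L.{2}[RK].{3}L.{6}L.{3}R))")


@dataclass(frozen=True)
class MotifHit:
    """One bHLH-interaction motif occurrence (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    matched: str


def find_bhlh_motifs(protein: str, protein_id: str = "") -> list[MotifHit]:
    """All 20-residue windows satisfying the bHLH-interaction pattern.

    Sequences shorter than 20 residues simply yield no hits.  Matching
    is case-insensitive; the wildcard positions accept X.
    """
    seq = protein.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise SequenceValidationError(
            f"non-amino-acid characters in sequence: {sorted(bad)}"
        )
    hits = []
    for m in _MOTIF_RE.finditer(seq):
        start = m.start() + 1
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=start,
                end=start + MOTIF_LEN - 1,
                matched=m.group(1),
            )
        )
    return hits


def scan_motifs(proteins: dict[str, str]) -> dict[str, list[MotifHit]]:
    """Motif scan over a whole protein set; ids without hits map to []."""
    return {pid: find_bhlh_motifs(seq, pid) for pid, seq in proteins.items()}
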