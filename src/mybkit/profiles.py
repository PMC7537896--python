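"""Repeat profiles: the scoring model for one MYB repeat unit.

A MYB repeat is an imperfect ~50-53 amino-acid module whose second and
third helices form a helix-turn-helix with three regularly spaced
tryptophan (or hydrophobic) core residues.  A :class:`RepeatProfile`
describes one such unit as a consensus sequence plus per-position
substitution scores (by default the BLOSUM62 row of each consensus
residue), together with the three tryptophan anchor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues accepted as a hydrophobic stand-in for a tryptophan anchor.
HYDROPHOBIC = set("WFYLIMV")

# Package-authored R2R3-type repeat consensus, 52 residues, tryptophans at
# 1-based positions 6 / 26 / 46 (regular ~20-residue spacing).  It is a
# default only: every scanning entry point accepts a replacement profile.
DEFAULT_CONSENSUS = "LKKGAWTEEEDQLLVDYIKTHGEGKWRSLPKRAGLKRCGKSCRLRWLNYLRP"


def blosum62_position_weights(consensus: str) -> np.ndarray:
    """Per-position substitution scores: row i is the BLOSUM62 row of
    ``consensus[i]`` over the 20 standard residues, shape (L, 20)."""
    mat = substitution_matrices.load("BLOSUM62")
    weights = np.empty((len(consensus), len(AMINO_ACIDS)), dtype=float)
    for i, c in enumerate(consensus):
        for j, aa in enumerate(AMINO_ACIDS):
            weights[i, j] = mat[c, aa]
    return weights


@dataclass
class RepeatProfile:
    """Consensus description of one MYB repeat.

    Parameters
    ----------
    name:
        Free-text profile name.
    consensus:
        Amino-acid consensus sequence (typically 50-53 residues).
    position_weights:
        Array of shape ``(len(consensus), 20)`` of substitution scores,
        columns ordered as :data:`AMINO_ACIDS`.  Defaults to BLOSUM62
        rows of the consensus residues.
    min_len, max_len:
        Accepted residue span of an intact repeat hit.
    w_anchors:
        Three strictly increasing 1-based consensus positions expected to
        hold tryptophan or another hydrophobic residue.
    """

    name: str = "R2R3-repeat"
    consensus: str = DEFAULT_CONSENSUS
    position_weights: np.ndarray | None = None
    min_len: int = 45
    max_len: int = 60
    w_anchors: tuple[int, int, int] = (6, 26, 46)

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not set(self.consensus) <= set(AMINO_ACIDS):
            bad = sorted(set(self.consensus) - set(AMINO_ACIDS))
            raise ValueError(f"non-standard residues in consensus: {bad}")
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if len(self.w_anchors) != 3:
            raise ValueError("exactly 3 tryptophan anchors required")
        if list(self.w_anchors) != sorted(set(self.w_anchors)):
            raise ValueError("w_anchors must be strictly increasing")
        if not all(1 <= a <= len(self.consensus) for a in self.w_anchors):
            raise ValueError("w_anchors out of consensus range")
        if self.position_weights is None:
            self.position_weights = blosum62_position_weights(self.consensus)
        self.position_weights = np.asarray(self.position_weights, dtype=float)
        if self.position_weights.shape != (len(self.consensus), len(AMINO_ACIDS)):
            raise ValueError(
                "position_weights must have shape (len(consensus), 20)"
            )

    @property
    def self_score(self) -> float:
        """Score of the consensus aligned gaplessly against itself."""
        idx = [AA_INDEX[c] for c in self.consensus]
        return float(self.position_weights[np.arange(len(idx)), idx].sum())


def match_mismatch_profile(
    consensus: str, match: float = 1.0, mismatch: float = -1.0, **kwargs
) -> RepeatProfile:
    """Profile with a flat match/mismatch scoring scheme (mainly for tests
    and worked examples where hand-computable scores are wanted)."""
    consensus = consensus.upper()
    weights = np.full((len(consensus), len(AMINO_ACIDS)), mismatch, dtype=float)
    for i, c in enumerate(consensus):
        weights[i, AA_INDEX[c]] = match
    return RepeatProfile(consensus=consensus, position_weights=weights, **kwargs)
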