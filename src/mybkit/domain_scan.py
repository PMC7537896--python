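"""Detection of tandem MYB repeats and domain-architecture typing.

The scanner mechanises the manual "intact MYB domain" inspection used
when curating a MYB family from whole-genome BLAST candidates: each
protein is searched with Smith-Waterman local alignment against a repeat
profile (position-specific substitution scores, linear gaps), the best
hit is recorded and masked, and the search repeats until no hit reaches
the score floor.  Proteins are then typed by repeat count
(0 -> none, 1 -> 1R, 2 -> R2R3, 3 -> 3R, >=4 -> 4R); only proteins with
two or more repeats are retained in the family catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SequenceValidationError
from .profiles import AA_INDEX, AMINO_ACIDS, HYDROPHOBIC, RepeatProfile

#: Default linear gap penalty for repeat-profile alignment.
DEFAULT_GAP = -6.0

#: Default score floor, as a fraction of the profile self-score.
DEFAULT_MIN_SCORE_FRAC = 0.5

MYB_TYPES = ("none", "1R", "R2R3", "3R", "4R")


@dataclass(frozen=True)
class RepeatHit:
    """One detected MYB repeat: 1-based inclusive protein coordinates."""

    start: int
    end: int
    score: float
    w_positions: tuple[int | None, int | None, int | None]
    anchor_matches: int
    rank: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MybArchitecture:
    """Repeat-count classification of one protein."""

    protein_id: str
    n_repeats: int
    myb_type: str
    hits: list[RepeatHit] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        """Whether the protein qualifies for the multi-repeat family."""
        return self.n_repeats >= 2


def _validate_protein(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceValidationError("empty protein sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise SequenceValidationError(
            f"non-amino-acid characters in sequence: {sorted(bad)}"
        )
    return seq


def _sw_matrix(window: str, profile: RepeatProfile, gap: float):
    """Smith-Waterman DP table of window (rows) vs consensus (cols)."""
    n, m = len(window), len(profile.consensus)
    widx = np.fromiter((AA_INDEX[c] for c in window), dtype=int, count=n)
    H = np.zeros((n + 1, m + 1), dtype=float)
    pw = profile.position_weights
    for i in range(1, n + 1):
        sub = pw[:, widx[i - 1]]
        row = H[i]
        prev = H[i - 1]
        # local alignment recurrence, linear gaps
        for j in range(1, m + 1):
            row[j] = max(
                0.0,
                prev[j - 1] + sub[j - 1],
                prev[j] + gap,
                row[j - 1] + gap,
            )
    return H, widx


def score_window(
    window: str, profile: RepeatProfile, gap_penalty: float = DEFAULT_GAP
) -> float:
    """Optimal local-alignment score of ``window`` against the profile
    consensus under the profile's position weights and linear gaps."""
    if gap_penalty >= 0:
        raise ConfigurationError("gap_penalty must be negative")
    window = _validate_protein(window)
    H, _ = _sw_matrix(window, profile, gap_penalty)
    return float(H.max())


def _traceback(H, window_idx, profile, gap, i, j):
    """Walk back from cell (i, j) to the local-alignment origin.

    Returns (start_i, aligned consensus-position -> window-position map),
    both 0-based.  Tie order diagonal > up > left keeps results
    deterministic.
    """
    pw = profile.position_weights
    colmap: dict[int, int] = {}
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = pw[j - 1, window_idx[i - 1]]
        if H[i, j] == H[i - 1, j - 1] + sub:
            colmap[j - 1] = i - 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return i, colmap


def _best_local_hit(segment: str, profile: RepeatProfile, gap: float):
    """Best local alignment of one unmasked segment; smallest-coordinate
    cell wins ties (np.argmax scans row-major, i.e. by end position)."""
    H, widx = _sw_matrix(segment, profile, gap)
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = float(H[i, j])
    if score <= 0:
        return None
    start_i, colmap = _traceback(H, widx, profile, gap, i, j)
    return score, start_i, i - 1, colmap  # 0-based inclusive window coords


def detect_repeats(
    protein: str,
    profile: RepeatProfile | None = None,
    min_score: float | None = None,
    gap_penalty: float = DEFAULT_GAP,
) -> list[RepeatHit]:
    """Greedy iterative repeat search.

    The best-scoring local hit at or above ``min_score`` is recorded and
    its residues are masked; the search repeats on the remaining
    unmasked stretches.  Hits are returned non-overlapping, sorted by
    start, ranked from the N-terminus.  A hit must span at least
    ``profile.min_len`` residues to count as an intact repeat.

    ``min_score`` defaults to half the profile self-score.
    """
    profile = profile or RepeatProfile()
    protein = _validate_protein(protein)
    if min_score is None:
        min_score = DEFAULT_MIN_SCORE_FRAC * profile.self_score
    if min_score <= 0:
        raise ConfigurationError("min_score must be positive")

    # unmasked segments as 0-based [start, end) protein intervals
    segments = [(0, len(protein))]
    raw_hits: list[RepeatHit] = []
    while True:
        best = None  # (score, abs_start, abs_end, colmap, seg_index)
        for k, (s, e) in enumerate(segments):
            if e - s < 1:
                continue
            found = _best_local_hit(protein[s:e], profile, gap_penalty)
            if found is None:
                continue
            score, i0, i1, colmap = found
            cand = (score, -(s + i0))  # ties -> smaller start coordinate
            if best is None or cand > (best[0], -best[1]):
                best = (score, s + i0, s + i1, colmap, k, s)
        if best is None or best[0] < min_score:
            break
        score, a0, a1, colmap, k, seg_off = best
        s, e = segments[k]
        segments[k : k + 1] = [(s, a0), (a1 + 1, e)]
        if a1 - a0 + 1 < profile.min_len:
            continue  # masked but not intact: too short to be a repeat
        w_positions = []
        n_match = 0
        for anchor in profile.w_anchors:
            wi = colmap.get(anchor - 1)
            if wi is None:
                w_positions.append(None)
            else:
                pos = seg_off + wi + 1
                w_positions.append(pos)
                if protein[pos - 1] in HYDROPHOBIC:
                    n_match += 1
        raw_hits.append(
            RepeatHit(
                start=a0 + 1,
                end=a1 + 1,
                score=score,
                w_positions=tuple(w_positions),
                anchor_matches=n_match,
            )
        )
    raw_hits.sort(key=lambda h: h.start)
    return [
        RepeatHit(
            start=h.start,
            end=h.end,
            score=h.score,
            w_positions=h.w_positions,
            anchor_matches=h.anchor_matches,
            rank=r,
        )
        for r, h in enumerate(raw_hits, start=1)
    ]


def classify_architecture(protein_id: str, hits: list[RepeatHit]) -> MybArchitecture:
    """Map a repeat-hit list to the domain-architecture vocabulary."""
    n = len(hits)
    myb_type = MYB_TYPES[min(n, 4)]
    return MybArchitecture(protein_id=protein_id, n_repeats=n, myb_type=myb_type, hits=hits)


def scan_proteins(
    proteins: dict[str, str],
    profile: RepeatProfile | None = None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    gap_penalty: float = DEFAULT_GAP,
) -> dict[str, MybArchitecture]:
    """Scan a whole protein set and classify each architecture."""
    profile = profile or RepeatProfile()
    min_score = min_score_frac * profile.self_score
    out = {}
    for pid, seq in proteins.items():
        hits = detect_repeats(seq, profile, min_score, gap_penalty)
        out[pid] = classify_architecture(pid, hits)
    return out
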