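"""Global alignment and master-alignment construction.

Needleman-Wunsch with flat match/mismatch scores and linear gaps serves
two roles: producing pairwise alignments for p-distance estimation and
seeding the center-star master alignment that the bootstrap stage
resamples column-wise.  Traceback ties resolve diagonal > up > left, so
alignments are deterministic.
"""

from __future__ import annotations

from .errors import SequenceValidationError
from .profiles import AMINO_ACIDS

GAP = "-"
_ALLOWED = set(AMINO_ACIDS) | {"X"}

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_SCORE = -2.0


def _check(seq: str, allow_empty: bool = False) -> str:
    seq = seq.upper()
    if not seq and not allow_empty:
        raise SequenceValidationError("empty sequence")
    bad = set(seq) - _ALLOWED
    if bad:
        raise SequenceValidationError(f"invalid residues: {sorted(bad)}")
    return seq


def global_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP_SCORE,
    allow_empty: bool = False,
) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment of two sequences under linear gaps.

    Returns ``(score, (aligned_a, aligned_b))``.  With ``allow_empty``
    the degenerate all-gap alignment of an empty sequence is permitted
    (score = len(other) * gap).
    """
    a = _check(a, allow_empty)
    b = _check(b, allow_empty)
    n, m = len(a), len(b)
    # score rows kept as plain lists: faster than elementwise numpy here
    prev = [j * gap for j in range(m + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up, 2 left
    ptr[0] = [2] * (m + 1)
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        ptr[i][0] = 1
        ai = a[i - 1]
        row_ptr = ptr[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = cur[j - 1] + gap
            # tie order: diagonal > up > left
            if diag >= up and diag >= left:
                cur[j], row_ptr[j] = diag, 0
            elif up >= left:
                cur[j], row_ptr[j] = up, 1
            else:
                cur[j], row_ptr[j] = left, 2
        prev = cur
    score = prev[m]
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i][j]
        if i > 0 and j > 0 and p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and p == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return float(score), ("".join(reversed(out_a)), "".join(reversed(out_b)))


def p_distance_aligned(a: str, b: str) -> tuple[float, int]:
    """p-distance over the gap-free columns of an aligned pair.

    Returns ``(distance, n_compared)``; a saturated pair with no
    comparable columns reports distance 1 (n_compared 0).
    """
    mismatches = 0
    compared = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return 1.0, 0
    return mismatches / compared, compared


def center_star_alignment(
    sequences: dict[str, str],
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP_SCORE,
) -> dict[str, str]:
    """Center-star multiple alignment.

    The center is the sequence with the highest total pairwise global
    alignment score (ties: lexicographically smallest id).  Every other
    sequence is aligned to the center and merged by projecting onto
    center coordinates ("once a gap, always a gap").
    """
    ids = sorted(sequences)
    if len(ids) == 1:
        return dict(sequences)
    totals = {i: 0.0 for i in ids}
    pair_aln: dict[tuple[str, str], tuple[str, str]] = {}
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1 :]:
            s, (aa, ab) = global_align(sequences[i], sequences[j], match, mismatch, gap)
            totals[i] += s
            totals[j] += s
            pair_aln[(i, j)] = (aa, ab)
    center = max(ids, key=lambda i: (totals[i], i))

    # merged center coordinates: list of (center_pos or None) per column
    center_seq = sequences[center]
    # gaps[k] = number of gap columns inserted before center position k
    gaps = [0] * (len(center_seq) + 1)
    aligned_to_center: dict[str, tuple[str, str]] = {}
    for other in ids:
        if other == center:
            continue
        key = (center, other) if (center, other) in pair_aln else (other, center)
        aa, ab = pair_aln[key]
        if key[0] != center:
            aa, ab = ab, aa
        aligned_to_center[other] = (aa, ab)
        k = 0
        run = 0
        local = [0] * (len(center_seq) + 1)
        for c in aa:
            if c == GAP:
                run += 1
            else:
                local[k] = run
                run = 0
                k += 1
        local[len(center_seq)] = run
        for k in range(len(center_seq) + 1):
            gaps[k] = max(gaps[k], local[k])

    def project(center_aln: str, other_aln: str) -> str:
        """Re-pad one pairwise alignment onto the merged gap pattern."""
        out = []
        k = 0  # center position index
        pending = []  # other residues sitting in gap columns before center pos k
        cols = list(zip(center_aln, other_aln))
        idx = 0
        for k in range(len(center_seq) + 1):
            pending = []
            while idx < len(cols) and cols[idx][0] == GAP:
                pending.append(cols[idx][1])
                idx += 1
            out.append("".join(pending).rjust(gaps[k], GAP))
            if idx < len(cols):
                out.append(cols[idx][1])
                idx += 1
        return "".join(out)

    merged: dict[str, str] = {}
    center_cols = []
    for k in range(len(center_seq) + 1):
        center_cols.append(GAP * gaps[k])
        if k < len(center_seq):
            center_cols.append(center_seq[k])
    merged[center] = "".join(center_cols)
    width = len(merged[center])
    for other in ids:
        if other == center:
            continue
        aa, ab = aligned_to_center[other]
        proj = project(aa, ab)
        assert len(proj) == width, (len(proj), width)
        merged[other] = proj
    return {i: merged[i] for i in ids}
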