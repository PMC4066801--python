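"""Affine-gap local alignment (Smith-Waterman / Gotoh) for pair identity.

A deliberately self-contained exact DP so that the identity statistic is
reproducible bit-for-bit: match +2, mismatch -3, a gap of length k costs
open + k*extend = 5 + 2k (BLASTN-like).  Traceback is deterministic: the
end cell is the highest-scoring cell with the smallest (row, column), and
moves prefer diagonal, then vertical, then horizontal.

Intended for ~300 bp repeat sequences; complexity is O(n*m).
"""

from __future__ import annotations

import numpy as np

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5   # charged once per gap
GAP_EXTEND = 2  # charged per gapped position

_NEG = -(10 ** 9)


def _validate(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


def _matrices(a: str, b: str):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in b (vertical)
    first_gap = -(GAP_OPEN + GAP_EXTEND)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] + first_gap, Ei[j - 1] - GAP_EXTEND)
            Fi[j] = max(Hp[j] + first_gap, Fp[j] - GAP_EXTEND)
            s = MATCH if ai == b[j - 1] else MISMATCH
            Hi[j] = max(0, Hp[j - 1] + s, Ei[j], Fi[j])
    return H, E, F


def local_alignment_score(seq_a: str, seq_b: str) -> int:
    """Score of the best local alignment under the fixed scoring scheme."""
    a, b = _validate(seq_a), _validate(seq_b)
    H, _, _ = _matrices(a, b)
    return int(H.max())


def local_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity (100 * matches / columns) of the best local alignment.

    Returns 0.0 when the best local score is 0 (no positive-scoring
    alignment exists).
    """
    a, b = _validate(seq_a), _validate(seq_b)
    H, E, F = _matrices(a, b)
    best = int(H.max())
    if best == 0:
        return 0.0
    flat = int(np.argmax(H))  # first occurrence: smallest (i, j)
    i, j = divmod(flat, H.shape[1])

    matches = columns = 0
    state = "H"
    first_gap = -(GAP_OPEN + GAP_EXTEND)
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if h == H[i - 1, j - 1] + s:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            columns += 1
            if F[i, j] == H[i - 1, j] + first_gap:
                state = "H"
            i -= 1
        else:  # E
            columns += 1
            if E[i, j] == H[i, j - 1] + first_gap:
                state = "H"
            j -= 1
    return 100.0 * matches / columns
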