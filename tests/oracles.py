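"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: placements are found
by exhaustive string comparison, hypergeometric tails by exact integer
combinatorics, and alignment scores by a textbook Gotoh dynamic program.
"""

from __future__ import annotations

from math import comb, inf


def equivalent_deletion_placements(ref: str, start: int, length: int) -> list[int]:
    """All start positions whose deletion yields the identical edited string."""
    target = ref[:start] + ref[start + length:]
    return [
        s for s in range(len(ref) - length + 1)
        if ref[:s] + ref[s + length:] == target
    ]


def brute_force_mh(ref: str, start: int, length: int) -> int:
    """Max k <= length with ref[start:start+k] == ref[start+length:start+length+k].

    Computed by whole-slice string comparison at every k, bounded by the
    reference end.
    """
    best = 0
    for k in range(1, length + 1):
        if start + length + k > len(ref):
            break
        if ref[start:start + k] == ref[start + length:start + length + k]:
            best = k
    return best


def hypergeom_tails_exact(a: int, n1: int, c: int, n2: int) -> tuple[float, float]:
    """(p_left, p_right) for the 2x2 table [[a, n1-a], [c, n2-c]].

    Exact integer enumeration of the hypergeometric pmf: the number of
    pattern reads among the guide's n1, conditioned on margins, is
    hypergeometric with population N = n1+n2, K = a+c successes, n1 draws.
    """
    N, K = n1 + n2, a + c
    denom = comb(N, n1)
    kmin, kmax = max(0, K - n2), min(K, n1)
    left = sum(comb(K, k) * comb(N - K, n1 - k) for k in range(kmin, a + 1))
    right = sum(comb(K, k) * comb(N - K, n1 - k) for k in range(max(a, kmin), kmax + 1))
    return left / denom, right / denom


def gotoh_score(ref: str, read: str, match: float = 2.0, mismatch: float = -3.0,
                gap_open: float = -8.0, gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap alignment score (Gotoh dynamic program).

    ``gap_open`` is the score of the first gapped position and
    ``gap_extend`` of each additional one.
    """
    n, m = len(ref), len(read)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def event_alignment_score(ref_len: int, events, match: float = 2.0,
                          mismatch: float = -3.0, gap_open: float = -8.0,
                          gap_extend: float = -1.0) -> float:
    """Score implied by an event list (matches fill all non-event positions)."""
    score = 0.0
    consumed = 0
    for ev in events:
        if ev.kind == "substitution":
            score += mismatch * ev.length
            consumed += ev.length
        else:
            score += gap_open + gap_extend * (ev.length - 1)
            if ev.kind == "deletion":
                consumed += ev.length
    score += match * (ref_len - consumed)
    return score
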