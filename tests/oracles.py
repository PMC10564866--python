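"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (exhaustive enumeration or textbook
dynamic programming) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def local_alignment_score_dp(
    a: str, b: str, match: int = 1, mismatch: int = -2, gap_open: int = 5, gap_extend: int = 2
) -> int:
    """Gotoh local alignment score; a gap of length L costs open + extend*L."""
    first_gap = gap_open + gap_extend
    la, lb = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    F = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration over all tables
    with the observed margins, in exact rational arithmetic.

    Tables whose hypergeometric probability is at most that of the
    observed table (up to the conventional 1 + 1e-7 relative slack for
    ties) contribute to p.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = prob(a)
    cutoff = p_obs * Fraction(10_000_001, 10_000_000)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = prob(k)
        if p_k <= cutoff:
            total += p_k
    return float(min(total, Fraction(1)))


def hamming1_edges_bruteforce(sequences: dict[str, str]) -> set[frozenset]:
    """All unordered pairs of equal-length sequences at Hamming distance 1."""
    ids = sorted(sequences)
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s, t = sequences[ids[i]], sequences[ids[j]]
            if len(s) != len(t):
                continue
            mismatches = sum(x != y for x, y in zip(s, t))
            if mismatches == 1:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


def levenshtein(a: str, b: str) -> int:
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def derep_greedy_oracle(records, threshold: float = 0.99) -> dict[str, str]:
    """Assign-to-first-seed greedy clustering in (duplicate_count, length)
    order; identity approximated as 1 - levenshtein/max-length.

    Returns a mapping member sequence_id -> seed sequence_id.
    """
    ordered = sorted(
        records, key=lambda r: (-r.duplicate_count, -len(r.sequence), r.sequence_id)
    )
    seeds = []
    assignment = {}
    for rec in ordered:
        for seed in seeds:
            la, lb = len(rec.sequence), len(seed.sequence)
            identity = 1.0 - levenshtein(rec.sequence, seed.sequence) / max(la, lb)
            if identity >= threshold:
                assignment[rec.sequence_id] = seed.sequence_id
                break
        else:
            seeds.append(rec)
            assignment[rec.sequence_id] = rec.sequence_id
    return assignment
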