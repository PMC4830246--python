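"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration or naive dynamic
programming, sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_protein_score(query: str, subject: str, open_cost: float = 11.0,
                     extend_cost: float = 1.0) -> float:
    """Naive Gotoh local alignment score, BLOSUM62, affine gaps.

    A gap of length k costs open_cost + (k-1) * extend_cost.
    """
    n, m = len(query), len(subject)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = _BLOSUM62[query[i - 1]][subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sw_nt_score(query: str, subject: str, mismatch: float = 2.0,
                gap: float = 3.0, match: float = 1.0) -> float:
    """Naive local alignment score with linear gap costs (per-base)."""
    n, m = len(query), len(subject)
    best = 0.0
    prev = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            s = match if query[i - 1] == subject[j - 1] else -mismatch
            cur[j] = max(0.0, prev[j - 1] + s, cur[j - 1] - gap, prev[j] - gap)
            best = max(best, cur[j])
        prev = cur
    return best


def best_interval_quadratic(scores) -> tuple[int, int]:
    """Maximal-sum contiguous interval by O(n^2) enumeration.

    Ties resolved leftmost start, then longest.  Sums accumulate left to
    right so floating-point results are bit-identical with a running-sum
    scan.  Returns (0, 0) when no interval has positive sum.
    """
    best_sum = 0.0
    best = (0, 0)
    n = len(scores)
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += scores[j]
            if total > best_sum:
                best_sum, best = total, (i, j + 1)
            elif total == best_sum and best_sum > 0:
                bi, bj = best
                if i < bi or (i == bi and j + 1 > bj):
                    best = (i, j + 1)
    return best


def lca_bruteforce(parent: dict, nodes) -> str:
    """LCA by explicit ancestor-path intersection; deepest common node."""
    paths = []
    for node in nodes:
        path = [node]
        while parent[path[-1]] != path[-1]:
            path.append(parent[path[-1]])
        paths.append(set(path))
    common = set.intersection(*paths)

    def depth(t):
        d = 0
        while parent[t] != t:
            t = parent[t]
            d += 1
        return d

    return max(common, key=depth)


def megan_candidates(pairs, max_hits: int = 5, min_fraction: float = 0.90):
    """Qualifying hit subjects under the MEGAN-style rule, re-derived.

    ``pairs`` is (subject_id, bit_score).  Scores strictly above
    min_fraction x top qualify (the top hit always does); the list is
    truncated to max_hits by descending score, ties by subject id.
    """
    ranked = sorted(pairs, key=lambda p: (-p[1], p[0]))
    top = ranked[0][1]
    keep = [s for s, b in ranked if b > min_fraction * top or b == top]
    return keep[:max_hits]


def bsr_decisions_bruteforce(custom_best, background_best, subject_to_family,
                             cutoffs) -> dict:
    """Recompute keep/discard decisions directly from the two best-hit tables.

    ``custom_best``/``background_best`` map read id -> (subject_id,
    bit_score); ``cutoffs`` maps family -> numeric cutoff.  Returns read
    id -> family for kept reads only.
    """
    kept = {}
    for rid, (subject, score) in custom_best.items():
        family = subject_to_family[subject]
        bg = background_best.get(rid)
        ratio = float("inf") if bg is None else score / bg[1]
        if ratio >= cutoffs[family]:
            kept[rid] = family
    return kept
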