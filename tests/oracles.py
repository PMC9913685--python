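"""Independent brute-force oracles the test suite checks the package against.

These are deliberately naive implementations — plain-Python exhaustive
dynamic programming for local alignment, explicit root-path intersection for
LCAs, and independent per-rank frequency tabulation for the agreement vote —
kept free of any code from the package's own fast paths.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_affine_score_oracle(
    q: str, s: str, match: int = 2, mismatch: int = -3,
    gap_open: int = 5, gap_extend: int = 2,
) -> int:
    """Exhaustive Gotoh DP, full matrix, plain Python.

    A gap of length L costs gap_open + L * gap_extend; transitions between
    the two gap states are allowed (each re-opens).  Returns the best local
    alignment raw score (0 when nothing positive exists).
    """
    n, m = len(q), len(s)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    go = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend,
                          F[i][j - 1] - go)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend,
                          E[i - 1][j] - go)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            prev = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1], 0.0)
            H[i][j] = max(0.0, prev + sub)
            best = max(best, H[i][j])
    return int(best)


def lca_oracle(paths: list[tuple[str, ...]]) -> str:
    """LCA by explicit intersection of root-paths (deepest common node)."""
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    for node in paths[0]:
        if node in common:
            return node
    raise AssertionError("no common ancestor")


def agreement_vote_oracle(
    lineages: list[dict[str, str]], ranks: tuple[str, ...], agreement: float
) -> tuple[str, str] | None:
    """Independent per-rank frequency tabulation of the agreement vote.

    ``lineages`` holds, per hit, a map rank → label for the ranks its
    lineage has.  Tabulates every rank independently (no early exit logic
    shared with the implementation) and returns the lowest rank at which
    some label reaches the agreement fraction of all hits, or None.
    """
    n = len(lineages)
    table: dict[str, dict[str, int]] = {r: {} for r in ranks}
    for lin in lineages:
        for r in ranks:
            if r in lin:
                lab = lin[r]
                table[r][lab] = table[r].get(lab, 0) + 1
    for r in ranks:
        for lab, cnt in sorted(table[r].items()):
            if cnt / n >= agreement - 1e-12:
                return lab, r
    return None
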