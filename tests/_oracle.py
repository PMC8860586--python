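"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions, not from the package
internals: islands are enumerated by checking every substring against
the island definition, and chains by memoized recursion over ordered
island selections.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_islands(seq: str, m: int, M: int) -> list[tuple[int, int, int, bool]]:
    """All (start, end, n_g, is_perfect) islands by substring definition check."""
    out = []
    n = len(seq)
    for i in range(n):
        for j in range(i + m, min(n, i + M + 2) + 1):
            sub = seq[i:j]
            if sub[0] != "G" or sub[-1] != "G":
                continue
            non_g = [k for k, c in enumerate(sub) if c != "G"]
            ng = len(sub) - len(non_g)
            if not (m <= ng <= M):
                continue
            if len(non_g) == 0:
                out.append((i, j, ng, True))
            elif len(non_g) == 1 and sub[non_g[0]] != "N":
                out.append((i, j, ng, False))
    return out


def naive_has_chain(
    seq: str,
    n: int,
    p: int,
    m: int = 3,
    M: int = 4,
    max_loop: int = 5,
    min_loop: int = 1,
    both_strands: bool = True,
) -> bool:
    """Existence of an n-island chain with >= p perfect islands."""

    def one_strand(s: str) -> bool:
        islands = sorted(naive_islands(s, m, M))
        max_bulged = n - p

        @lru_cache(maxsize=None)
        def reach(idx: int, k: int, bulged: int) -> bool:
            # chain of k more islands after islands[idx]
            if k == 0:
                return True
            _, end, _, _ = islands[idx]
            for j, (s2, e2, ng2, perf2) in enumerate(islands):
                loop = s2 - end
                if loop < min_loop or loop > max_loop:
                    continue
                b2 = bulged + (0 if perf2 else 1)
                if b2 > max_bulged:
                    continue
                if reach(j, k - 1, b2):
                    return True
            return False

        for i, (_, _, _, perf) in enumerate(islands):
            b0 = 0 if perf else 1
            if b0 <= max_bulged and reach(i, n - 1, b0):
                return True
        return False

    if one_strand(seq):
        return True
    return both_strands and one_strand(rc(seq))


def naive_max_units(seq: str, m=3, M=4, max_loop=5, min_loop=1, both_strands=True) -> int:
    """Largest k with a chain of 4k islands (no perfection quota)."""

    def longest(s: str) -> int:
        islands = sorted(naive_islands(s, m, M))

        @lru_cache(maxsize=None)
        def best_from(idx: int) -> int:
            _, end, _, _ = islands[idx]
            top = 1
            for j, (s2, _, _, _) in enumerate(islands):
                if min_loop <= s2 - end <= max_loop:
                    top = max(top, 1 + best_from(j))
            return top

        return max((best_from(i) for i in range(len(islands))), default=0)

    chains = longest(seq)
    if both_strands:
        chains = max(chains, longest(rc(seq)))
    return chains // 4


def hypergeom_upper_tail_exhaustive(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for a hypergeometric draw, by counting all C(N, n) draws."""
    total = comb(N, n)
    hits = sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(n, K) + 1)
    )
    return hits / total
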