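"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives the expected behaviour from first principles (dynamic
programming, exhaustive enumeration, O(n^2) formulas) without touching the
package's own code paths.
"""

from __future__ import annotations

import math
from collections import Counter


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (unit costs)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


class _revstr(str):
    """String with inverted comparison order (for max() tie-breaking)."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def greedy_collapse_oracle(umi_read_counts: dict[str, int], threshold: int) -> dict[str, str]:
    """Exhaustive restatement of the greedy UMI-collapse rule.

    All pairwise distances are enumerated; the UMI with the most matches
    among survivors (ties: more reads, then lexicographically first) absorbs
    its matches; both leave the pool; repeat until no survivor has a match.
    """
    umis = sorted(umi_read_counts)
    dist = {
        (a, b): levenshtein_dp(a, b)
        for i, a in enumerate(umis)
        for b in umis[i + 1 :]
    }

    def matched(a: str, pool: set[str]) -> set[str]:
        out = set()
        for b in pool:
            if b == a:
                continue
            d = dist.get((a, b)) if (a, b) in dist else dist[(b, a)]
            if d <= threshold:
                out.add(b)
        return out

    mapping: dict[str, str] = {}
    pool = set(umis)
    while True:
        candidates = [(u, matched(u, pool)) for u in pool]
        candidates = [(u, m) for u, m in candidates if m]
        if not candidates:
            break
        seed, absorbed = max(
            candidates,
            key=lambda um: (len(um[1]), umi_read_counts[um[0]], _revstr(um[0])),
        )
        mapping[seed] = seed
        for u in absorbed:
            mapping[u] = seed
        pool -= absorbed
        pool.discard(seed)
    for u in pool:
        mapping[u] = u
    return mapping


def majority_call_oracle(bases: list[str]) -> str:
    """Per-UMI mutant/wild-type call by direct counting (OTHER ignored)."""
    n_wt = bases.count("WT")
    n_mut = bases.count("MUT")
    if n_wt == 0 and n_mut == 0:
        return "NONE"
    if n_mut > n_wt:
        return "MUT"
    if n_wt > n_mut:
        return "WT"
    return "AMBIGUOUS"


def consensus_oracle(bases: list[str], threshold: float = 0.75) -> str:
    """Most-common-base rule with a share threshold, by direct enumeration."""
    if not bases:
        return "DISCARDED"
    counts = Counter(bases)
    top = max(counts.values())
    leaders = [b for b, n in counts.items() if n == top]
    if len(leaders) > 1:
        return "DISCARDED"
    if top / len(bases) < threshold:
        return "DISCARDED"
    return leaders[0] if leaders[0] in ("WT", "MUT") else "DISCARDED"


def hypergeom_tail_oracle(k: int, m: int, s: int, u: int) -> float:
    """P(overlap >= k) for marker set of size m and signature of size s in a
    universe of u genes, by exhaustive summation of the hypergeometric pmf."""
    total = math.comb(u, m)
    p = 0.0
    for j in range(k, min(m, s) + 1):
        p += math.comb(s, j) * math.comb(u - s, m - j) / total
    return min(p, 1.0)


def gini_pairwise_oracle(sizes) -> float:
    """Gini index by the O(n^2) mean-absolute-difference definition."""
    xs = list(map(float, sizes))
    n = len(xs)
    mean = sum(xs) / n
    total = sum(abs(a - b) for a in xs for b in xs)
    return total / (2.0 * n * n * mean)


def zipf_mle_alpha(sizes, lo: float = 1.05, hi: float = 10.0) -> float:
    """Maximum-likelihood exponent of a zeta (discrete power-law) sample by
    golden-section search over the log-likelihood."""
    from scipy.special import zeta as zeta_fn
    import numpy as np

    x = np.asarray(sizes, dtype=float)
    slog = np.log(x).sum()
    n = len(x)

    def nll(a: float) -> float:
        return a * slog + n * math.log(zeta_fn(a, 1))

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    for _ in range(200):
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        if nll(c) < nll(d):
            b = d
        else:
            a = c
    return (a + b) / 2.0
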