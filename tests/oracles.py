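"""Independent reference implementations used only to check the package.

These deliberately avoid the package's algorithms: the matcher oracle is a
brute-force scan over every offset of every reference, and the local-
alignment oracle is a memoized recursive formulation of the affine-gap
local alignment recurrence (score only).
"""

from __future__ import annotations

from functools import lru_cache

_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_matches(read_seq, read_id, catalog, policy):
    """Every full-read exact occurrence, by scanning all offsets."""
    L = len(read_seq)
    if L < policy.min_len:
        return []
    if policy.max_len is not None and L > policy.max_len:
        return []
    if "N" in read_seq:
        return []
    probes = [("+", read_seq)]
    if policy.strands == "both":
        probes.append(("-", brute_force_revcomp(read_seq)))
    out = []
    for rec in catalog:
        for strand, probe in probes:
            for off in range(rec.length - L + 1):
                if rec.sequence[off : off + L] == probe:
                    out.append((rec.id, off, off + L, strand))
    out.sort(key=lambda t: (t[0], t[1], t[3]))
    return out


def local_alignment_score(
    q: str, s: str,
    match: float = 2.0, mismatch: float = -3.0,
    gap_open: float = -5.0, gap_extend: float = -2.0,
) -> float:
    """Best affine-gap local alignment score via memoized recursion.

    A gap of length L costs gap_open + (L-1)*gap_extend. Only suitable for
    short sequences (state space 3*(n+1)*(m+1)).
    """
    n, m = len(q), len(s)
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def h(i: int, j: int) -> float:
        # best local alignment score ending at q[:i], s[:j] (possibly empty)
        if i == 0 or j == 0:
            return 0.0
        sub = match if q[i - 1] == s[j - 1] and q[i - 1] != "N" else mismatch
        return max(0.0, h(i - 1, j - 1) + sub, e(i, j), f(i, j))

    @lru_cache(maxsize=None)
    def e(i: int, j: int) -> float:
        # ends in a gap consuming s[j-1]
        if j == 0:
            return NEG
        if j == 1:
            return h(i, 0) + gap_open
        return max(h(i, j - 1) + gap_open, e(i, j - 1) + gap_extend)

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == 0:
            return NEG
        if i == 1:
            return h(0, j) + gap_open
        return max(h(i - 1, j) + gap_open, f(i - 1, j) + gap_extend)

    best = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            best = max(best, h(i, j))
    return best


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle preserving (approximately) dinucleotide content: random walk
    over the observed dinucleotide multiset."""
    if len(seq) < 3:
        return seq
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    idx = list(range(len(pairs)))
    rng.shuffle(idx)
    out = [pairs[idx[0]]]
    used = {idx[0]}
    for _ in range(len(seq) - 2):
        last = out[-1][-1]
        nxt = next((k for k in idx if k not in used and pairs[k][0] == last), None)
        if nxt is None:
            nxt = next(k for k in idx if k not in used)
        used.add(nxt)
        out.append(pairs[nxt])
    return out[0] + "".join(p[1] for p in out[1:])
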