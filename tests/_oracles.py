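"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming aligners: local
alignment scores are obtained by enumerating every alignment of every
substring pair, global scores by enumerating every alignment path.
"""

from __future__ import annotations

from functools import lru_cache

NUC_MATCH = 1
NUC_MISMATCH = -2
GAP_OPEN = 5  # gap of length k costs GAP_OPEN + GAP_EXTEND * k
GAP_EXTEND = 2


def _score_pair(x: str, y: str) -> int:
    return NUC_MATCH if x == y and x != "N" else NUC_MISMATCH


def global_score_enumerate(a: str, b: str) -> float:
    """Best global alignment score by exhaustive path enumeration."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e18
        if i < len(a) and j < len(b):
            best = max(best, _score_pair(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = GAP_EXTEND if prev == "d" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i + 1, j, "d"))
        if j < len(b):
            cost = GAP_EXTEND if prev == "i" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i, j + 1, "i"))
        return best

    out = rec(0, 0, "s")
    rec.cache_clear()
    return out


def local_score_enumerate(a: str, b: str) -> float:
    """Best local alignment score: max global score over all substring pairs."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_score_enumerate(a[i1:i2], b[j1:j2]))
    return best


def all_orfs_enumerate(seq: str, min_aa: int = 100) -> set:
    """Every ATG..stop (or frame-end) span of >= min_aa codons, six frames,
    as forward-strand half-open nucleotide spans."""
    from Bio.Seq import Seq

    comp = str.maketrans("ACGTN", "TGCAN")
    out = set()
    L = len(seq)
    for strand in (1, -1):
        s = seq if strand == 1 else seq.translate(comp)[::-1]
        for off in range(3):
            aa = str(Seq(s[off : off + 3 * ((L - off) // 3)]).translate())
            for i, ch in enumerate(aa):
                if ch != "M":
                    continue
                stop = aa.find("*", i)
                end = stop if stop != -1 else len(aa)
                if end - i < min_aa:
                    continue
                p_end = end + 1 if stop != -1 else end
                ns, ne = off + 3 * i, off + 3 * p_end
                if strand == 1:
                    out.add((ns, ne))
                else:
                    out.add((L - ne, L - ns))
    return out
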