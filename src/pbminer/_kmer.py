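"""Vectorized exact k-mer seeding shared by the protein and nucleotide searches."""

from __future__ import annotations

import numpy as np

_NUC_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _NUC_CODE[b] = i

_PROT_ALPHA = "ACDEFGHIKLMNPQRSTVWY"
_PROT_CODE = np.full(256, 255, dtype=np.uint8)  # X, * and '-' stay invalid
for i, b in enumerate(_PROT_ALPHA.encode()):
    _PROT_CODE[b] = i


def encode(seq: str, protein: bool = False) -> np.ndarray:
    """Residue codes (uint8); 255 marks characters excluded from seeding."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return (_PROT_CODE if protein else _NUC_CODE)[raw]


def rolling_kmer_codes(codes: np.ndarray, k: int, base: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of every k-mer plus a validity mask (no excluded residues).

    Returns ``(values, valid)`` of length ``len(codes) - k + 1``.
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        window = codes[j : j + m]
        vals = vals * base + window
        valid &= window != 255
    return vals, valid


class KmerIndex:
    """Sorted index of k-mer codes of one subject string for exact-match lookup."""

    def __init__(self, seq: str, k: int, protein: bool = False):
        self.k = k
        base = 32 if protein else 4
        vals, valid = rolling_kmer_codes(encode(seq, protein), k, base)
        self._base = base
        self._protein = protein
        pos = np.nonzero(valid)[0]
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self._sorted_vals = vals[order]
        self._sorted_pos = pos[order].astype(np.int64)

    def lookup(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """All exact seed matches: arrays (query_pos, subject_pos)."""
        qvals, qvalid = rolling_kmer_codes(
            encode(query, self._protein), self.k, self._base
        )
        qpos_all = np.nonzero(qvalid)[0]
        qvals = qvals[qpos_all]
        lo = np.searchsorted(self._sorted_vals, qvals, side="left")
        hi = np.searchsorted(self._sorted_vals, qvals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qp = np.repeat(qpos_all, counts)
        sp = np.empty(total, dtype=np.int64)
        o = 0
        for l, h in zip(lo, hi):
            c = h - l
            if c:
                sp[o : o + c] = self._sorted_pos[l:h]
                o += c
        return qp, sp
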