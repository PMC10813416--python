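"""ORF prediction and transposase domain characterization.

piggyBac transposases carry five recognizable regions: an N-terminal
domain (NTD), two dimerization/DNA-binding domains (DDBD1, DDBD2), the
catalytic DDD triad (three aspartates at family-typical spacings: D1-D2
roughly 78-85 aa, D2-D3 roughly 98-113 aa) and a C-terminal cysteine-rich
domain (CRD) of eight regularly spaced cysteines.  This module locates all
of them with rule-based scans, profiles the conserved 5' TIR motifs
(CACTA/CCCTC/CCCTT/CCCAT), and computes within/between-clade pairwise
identity tables.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np

from .seqcore import (
    NucSequence,
    ProtSequence,
    needleman_wunsch,
    six_frame_translate,
)

TIR_MOTIF_CLASSES = ("CACTA", "CCCTC", "CCCTT", "CCCAT")

# strict spacing envelopes observed across the seven clades
DDD_D1_D2_STRICT = (78, 85)
DDD_D2_D3_STRICT = (98, 113)


@dataclass
class OrfCall:
    nuc_span: tuple[int, int]  # forward-strand element coordinates, half-open
    strand: str
    frame: int
    protein: ProtSequence
    length_aa: int


@dataclass
class CrdCall:
    cys_positions: tuple[int, ...]
    window: tuple[int, int]
    regularity: float  # stdev of inter-cysteine gaps (reported, not thresholded)


@dataclass
class DomainAnnotation:
    ddd: tuple[int, int, int] | None
    d1_d2_spacing: int | None
    d2_d3_spacing: int | None
    crd: tuple[int, ...] | None
    ntd_span: tuple[int, int] | None
    ddbd1_span: tuple[int, int] | None
    ddbd2_span: tuple[int, int] | None


def find_orfs(
    element_seq: str | NucSequence, min_aa: int = 100
) -> tuple[list[OrfCall], OrfCall | None]:
    """All ATG-to-stop spans of >= min_aa residues on all six frames.

    Each ATG opens one ORF ending at the first in-frame stop (or the frame
    end).  Returns the list plus the longest call (the putative
    transposase); ties break toward the smallest forward-strand start.
    """
    seq = element_seq if isinstance(element_seq, NucSequence) else NucSequence("elem", element_seq)
    if len(seq) < 3:
        raise ValueError("element shorter than one codon")
    calls: list[OrfCall] = []
    for frame in six_frame_translate(seq):
        aa = frame.protein.residues
        # first in-frame stop at/after each position
        next_stop = [len(aa)] * (len(aa) + 1)
        for i in range(len(aa) - 1, -1, -1):
            next_stop[i] = i if aa[i] == "*" else next_stop[i + 1]
        for i, ch in enumerate(aa):
            if ch != "M":
                continue
            stop = next_stop[i]
            length = stop - i
            if length < min_aa:
                continue
            has_stop = stop < len(aa)
            p_end = stop + 1 if has_stop else stop
            span = frame.nuc_span(i, p_end)
            calls.append(
                OrfCall(
                    nuc_span=span,
                    strand="+" if frame.frame > 0 else "-",
                    frame=frame.frame,
                    protein=ProtSequence(
                        f"{seq.id}|orf{len(calls) + 1}", aa[i:stop] + ("*" if has_stop else "")
                    ),
                    length_aa=length,
                )
            )
    calls.sort(key=lambda c: (-c.length_aa, c.nuc_span[0], c.strand))
    longest = calls[0] if calls else None
    calls_sorted = sorted(calls, key=lambda c: (c.nuc_span, c.frame))
    return calls_sorted, longest


def _interval_distance(x: int, lo: int, hi: int) -> int:
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0


def locate_ddd(
    protein: str | ProtSequence,
    d1_d2_range: tuple[int, int] = (70, 95),
    d2_d3_range: tuple[int, int] = (90, 120),
) -> tuple[int, int, int] | None:
    """The catalytic aspartate triad, or None.

    All D-triples with spacings inside the (widened) search ranges are
    enumerated; the winner is the triple whose spacings are closest (L1)
    to the strict observed envelopes, ties broken toward the most
    N-terminal D1.
    """
    aa = protein.residues if hasattr(protein, "residues") else protein
    ds = [i for i, ch in enumerate(aa) if ch == "D"]
    best = None
    best_key = None
    for i, d1 in enumerate(ds):
        for d2 in ds[i + 1 :]:
            s12 = d2 - d1
            if s12 > d1_d2_range[1]:
                break
            if s12 < d1_d2_range[0]:
                continue
            for d3 in ds:
                s23 = d3 - d2
                if s23 < d2_d3_range[0]:
                    continue
                if s23 > d2_d3_range[1]:
                    break
                key = (
                    _interval_distance(s12, *DDD_D1_D2_STRICT)
                    + _interval_distance(s23, *DDD_D2_D3_STRICT),
                    d1,
                    d2,
                )
                if best_key is None or key < best_key:
                    best_key, best = key, (d1, d2, d3)
    return best


def locate_crd(
    protein: str | ProtSequence, window: int = 120, n_cys: int = 8
) -> CrdCall | None:
    """The cysteine-rich domain: max-cysteine window over the C-terminal third."""
    aa = protein.residues if hasattr(protein, "residues") else protein
    L = len(aa)
    if L < window:
        return None
    start_min = (2 * L) // 3
    start_min = min(start_min, L - window)
    best_start, best_count = None, -1
    cys = np.array([1 if c == "C" else 0 for c in aa])
    csum = np.concatenate([[0], np.cumsum(cys)])
    for s in range(start_min, L - window + 1):
        c = int(csum[s + window] - csum[s])
        if c > best_count:
            best_count, best_start = c, s
    if best_count < n_cys or best_start is None:
        return None
    positions = tuple(
        i for i in range(best_start, best_start + window) if aa[i] == "C"
    )[:n_cys]
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    reg = statistics.pstdev(gaps) if len(gaps) > 1 else 0.0
    return CrdCall(cys_positions=positions, window=(best_start, best_start + window), regularity=reg)


def annotate_domains(protein: str | ProtSequence) -> DomainAnnotation:
    """Coarse five-domain layout positioned relative to the DDD triad.

    The NTD/DDBD spans are heuristic by design: DDBD1 is the 100 aa
    preceding D1, the NTD precedes it, DDBD2 runs from D3 to the CRD.
    """
    aa = protein.residues if hasattr(protein, "residues") else protein
    ddd = locate_ddd(aa)
    crd = locate_crd(aa)
    if ddd is None:
        return DomainAnnotation(None, None, None, crd.cys_positions if crd else None,
                                None, None, None)
    d1, d2, d3 = ddd
    ddbd1 = (max(0, d1 - 100), d1)
    ntd = (0, ddbd1[0])
    crd_start = crd.window[0] if crd else len(aa)
    ddbd2 = (d3 + 1, max(d3 + 1, crd_start))
    return DomainAnnotation(
        ddd=ddd,
        d1_d2_spacing=d2 - d1,
        d2_d3_spacing=d3 - d2,
        crd=crd.cys_positions if crd else None,
        ntd_span=ntd,
        ddbd1_span=ddbd1,
        ddbd2_span=ddbd2,
    )


@dataclass
class TirMotifProfile:
    counts: np.ndarray  # 20 x 4 counts over A,C,G,T
    motif_classes: list[str]  # per input TIR

    @property
    def class_fractions(self) -> dict[str, float]:
        n = len(self.motif_classes)
        out: dict[str, float] = {}
        for m in list(TIR_MOTIF_CLASSES) + ["other"]:
            c = self.motif_classes.count(m)
            if c:
                out[m] = c / n
        return out

    def to_table(self) -> str:
        lines = ["pos\tA\tC\tG\tT"]
        for i, row in enumerate(self.counts):
            lines.append(f"{i + 1}\t" + "\t".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"


def tir_motif_profile(tirs: list[str | NucSequence]) -> TirMotifProfile:
    """Per-position base counts over the first 20 bp of 5' TIRs and the
    conserved 5-mer motif class of each."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((20, 4), dtype=int)
    classes = []
    for t in tirs:
        s = t.residues if hasattr(t, "residues") else str(t).upper()
        if len(s) < 5:
            raise ValueError("TIR shorter than 5 bp cannot be motif-classified")
        classes.append(s[:5] if s[:5] in TIR_MOTIF_CLASSES else "other")
        for i, ch in enumerate(s[:20]):
            if ch in base_idx:
                counts[i, base_idx[ch]] += 1
    return TirMotifProfile(counts=counts, motif_classes=classes)


def identity_matrix(
    sequences: list, clades: list[str], protein: bool | None = None
) -> tuple[np.ndarray, list[str], dict[str, float], dict[tuple[str, str], float]]:
    """All-vs-all global identities plus within/between-clade means.

    Returns (matrix, clade labels per row, within-clade means over
    distinct pairs, between-clade means keyed by sorted clade pairs).
    """
    if len(sequences) < 2:
        raise ValueError("identity_matrix needs at least two sequences")
    n = len(sequences)
    if len(clades) != n:
        raise ValueError("one clade label per sequence required")
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = needleman_wunsch(sequences[i], sequences[j], protein=protein).identity
            m[i, j] = m[j, i] = ident
    within: dict[str, list[float]] = {}
    between: dict[tuple[str, str], list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = clades[i], clades[j]
            if a == b:
                within.setdefault(a, []).append(m[i, j])
            else:
                between.setdefault(tuple(sorted((a, b))), []).append(m[i, j])
    w = {k: float(np.mean(v)) for k, v in within.items()}
    b = {k: float(np.mean(v)) for k, v in between.items()}
    return m, list(clades), w, b
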