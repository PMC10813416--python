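"""Kimura 2-parameter divergence of copies vs their consensus, and binned
divergence landscapes.

K2P distinguishes transition (P) and transversion (Q) proportions:

    K = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Low K marks recent insertions.  The landscape accumulates copy base pairs
into integer-percent divergence bins, normalized by genome length, so each
family's amplification history reads as a peak (recent burst near zero,
old invasion at high K, recurrent waves as multimodality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boundaries import CopyHit, ElementModel
from .seqcore import NucSequence, needleman_wunsch, reverse_complement

SATURATION_CAP = 3.0

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class DivergenceEstimate:
    P: float
    Q: float
    K: float
    sites: int
    saturated: bool = False


def k2p(aligned_a: str, aligned_b: str) -> DivergenceEstimate:
    """K2P estimate from two gapped rows; gap and N columns are excluded.

    Saturated pairs (log arguments <= 0) get K = SATURATION_CAP, flagged.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows must have equal length")
    sites = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return DivergenceEstimate(P=P, Q=Q, K=SATURATION_CAP, sites=sites, saturated=True)
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DivergenceEstimate(P=P, Q=Q, K=K, sites=sites)


def copy_divergences(
    copies: list[CopyHit],
    consensus: NucSequence,
    genome,
    min_sites: int = 50,
) -> list[tuple[CopyHit, DivergenceEstimate]]:
    """K2P of each genomic copy against the family consensus.

    Each copy is extracted from the genome (minus-strand copies are
    reverse-complemented first), globally aligned to the consensus, and
    fed to :func:`k2p`.  Copies with fewer than ``min_sites`` comparable
    sites are skipped.
    """
    contigs = {c.id: c for c in ([genome] if isinstance(genome, NucSequence) else genome)}
    out = []
    for hit in copies:
        contig = contigs[hit.contig]
        seq = contig.residues[hit.span[0] : hit.span[1]]
        if hit.strand == "-":
            seq = reverse_complement(seq)
        aln = needleman_wunsch(consensus.residues, seq, protein=False)
        try:
            est = k2p(aln.aligned_query, aln.aligned_subject)
        except ValueError:
            continue
        if est.sites < min_sites:
            continue
        out.append((hit, est))
    return out


@dataclass
class Landscape:
    """Per-bin genome coverage of transposon copies by divergence percent."""

    bin_width: int
    n_bins: int
    genome_length: int
    per_type: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_saturated_bp: int = 0

    @property
    def total(self) -> np.ndarray:
        out = np.zeros(self.n_bins)
        for v in self.per_type.values():
            out += v
        return out

    def to_table(self) -> str:
        lines = ["bin_pct\ttype_id\tcoverage_pct"]
        for tid in sorted(self.per_type):
            for b, cov in enumerate(self.per_type[tid]):
                if cov > 0:
                    lines.append(f"{b * self.bin_width}\t{tid}\t{cov:.6f}")
        return "\n".join(lines) + "\n"


def landscape(
    divergences: list[tuple[str, int, DivergenceEstimate]],
    genome_length: int,
    bin_width: int = 1,
    max_pct: int = 50,
) -> Landscape:
    """Bin copy base pairs by K (percent) into right-open percent bins.

    ``divergences`` holds (type_id, copy_length_bp, estimate) triples.
    Coverage per bin is 100 * bp / genome_length; saturated copies are
    excluded from the bins and tallied separately.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    n_bins = max_pct // bin_width
    ls = Landscape(bin_width=bin_width, n_bins=n_bins, genome_length=genome_length)
    for type_id, length_bp, est in divergences:
        if est.saturated:
            ls.excluded_saturated_bp += length_bp
            continue
        b = int(100.0 * est.K) // bin_width
        if b >= n_bins:
            ls.excluded_saturated_bp += length_bp
            continue
        if type_id not in ls.per_type:
            ls.per_type[type_id] = np.zeros(n_bins)
        ls.per_type[type_id][b] += 100.0 * length_bp / genome_length
    return ls


def element_landscape(
    elements: list[ElementModel], genome, bin_width: int = 1
) -> Landscape:
    """Convenience: divergences of every element's copies, binned."""
    contigs = [genome] if isinstance(genome, NucSequence) else list(genome)
    glen = sum(len(c) for c in contigs)
    triples = []
    for el in elements:
        if el.consensus is None:
            continue
        for hit, est in copy_divergences(el.copy_hits, el.consensus, genome):
            triples.append((el.type_id, hit.span[1] - hit.span[0], est))
    return landscape(triples, glen, bin_width=bin_width)
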