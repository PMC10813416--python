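"""Translated homology search: protein queries vs six-frame genome translation.

The search is a classic seed-and-extend: exact protein k-mer seeds on all
six reading frames, diagonal-band grouping with a two-seed trigger, local
Smith-Waterman extension, and Karlin-Altschul E-value filtering over a
search space of both genome strands.  Surviving hits are filtered on query
coverage and identity, then merged into candidate loci extended by flanking
sequence for downstream boundary detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmer import KmerIndex
from .seqcore import (
    AlignmentResult,
    NucSequence,
    ProtSequence,
    karlin_altschul_evalue,
    six_frame_translate,
    smith_waterman,
)


@dataclass
class MiningConfig:
    """Every numeric threshold of the mining protocol in one place."""

    evalue_cutoff: float = 1e-4
    min_hit_coverage: float = 0.30
    min_hit_identity: float = 0.80
    flank_bp: int = 4000
    merge_gap_bp: int = 3000
    seed_word_size: int = 4
    copy_min_coverage: float = 0.40
    copy_min_identity: float = 0.80
    intact_min_transposase_aa: int = 500
    cluster_identity: float = 0.50
    # seeding heuristics
    min_band_seeds: int = 2
    band_diag_slack: int = 3
    band_pos_gap: int = 400
    copy_seed_k: int = 12
    copy_min_seeds: int = 3

    def violations(self) -> list[str]:
        out = []
        for name in (
            "min_hit_coverage",
            "min_hit_identity",
            "copy_min_coverage",
            "copy_min_identity",
            "cluster_identity",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                out.append(f"{name} must be in (0, 1], got {v}")
        if self.evalue_cutoff <= 0:
            out.append(f"evalue_cutoff must be positive, got {self.evalue_cutoff}")
        for name in ("flank_bp", "merge_gap_bp", "seed_word_size",
                     "intact_min_transposase_aa"):
            if getattr(self, name) < 0:
                out.append(f"{name} must be nonnegative, got {getattr(self, name)}")
        return out


@dataclass
class TranslatedHit:
    """One filtered protein-vs-translated-genome alignment."""

    query_id: str
    contig: str
    strand: str
    frame: int
    nuc_span: tuple[int, int]
    score: float
    identity: float
    coverage_query: float
    evalue: float
    alignment: AlignmentResult | None = None


@dataclass
class CandidateLocus:
    """A merged hit region plus flanking sequence, ready for annotation."""

    locus_id: str
    contig: str
    core_span: tuple[int, int]
    extended_span: tuple[int, int]
    sequence: NucSequence
    source_hits: list[TranslatedHit] = field(default_factory=list)

    @property
    def core_in_locus(self) -> tuple[int, int]:
        """Core span in locus-local coordinates."""
        off = self.extended_span[0]
        return self.core_span[0] - off, self.core_span[1] - off


def _as_contigs(genome) -> list[NucSequence]:
    if isinstance(genome, NucSequence):
        return [genome]
    return list(genome)


def _band_groups(qpos: np.ndarray, spos: np.ndarray, diag_slack: int, pos_gap: int):
    """Group seed matches into diagonal bands; yields index arrays."""
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    d, s = diag[order], spos[order]
    brk = np.nonzero((np.diff(d) > diag_slack) | (np.abs(np.diff(s)) > pos_gap))[0] + 1
    for chunk in np.split(order, brk):
        if len(chunk):
            yield chunk


def search_genome(
    genome, queries: list[ProtSequence], cfg: MiningConfig | None = None
) -> list[TranslatedHit]:
    """Seed-and-extend translated search of all six frames of every contig.

    E-values use m = query length (aa) and n = 2 x total genome length
    (both strands); hits above the E-value cutoff are discarded.
    """
    cfg = cfg or MiningConfig()
    contigs = _as_contigs(genome)
    if not contigs or not queries:
        raise ValueError("search_genome requires a genome and at least one query")
    total_n = 2 * sum(len(c) for c in contigs)
    hits: list[TranslatedHit] = []
    for contig in contigs:
        for frame in six_frame_translate(contig):
            fseq = frame.protein.residues
            if len(fseq) < cfg.seed_word_size:
                continue
            index = KmerIndex(fseq, cfg.seed_word_size, protein=True)
            for query in queries:
                qp, sp = index.lookup(query.residues)
                if len(qp) == 0:
                    continue
                for band in _band_groups(
                    qp, sp, cfg.band_diag_slack, cfg.band_pos_gap
                ):
                    if len(band) < cfg.min_band_seeds:
                        continue
                    lo = max(0, int(sp[band].min()) - len(query))
                    hi = min(len(fseq), int(sp[band].max()) + cfg.seed_word_size + len(query))
                    window = fseq[lo:hi]
                    aln = smith_waterman(query.residues, window, protein=True)
                    if aln.is_empty:
                        continue
                    ev = karlin_altschul_evalue(aln.score, len(query), total_n)
                    if ev > cfg.evalue_cutoff:
                        continue
                    span = frame.nuc_span(lo + aln.subject_start, lo + aln.subject_end)
                    hits.append(
                        TranslatedHit(
                            query_id=query.id,
                            contig=contig.id,
                            strand="+" if frame.frame > 0 else "-",
                            frame=frame.frame,
                            nuc_span=span,
                            score=aln.score,
                            identity=aln.identity,
                            coverage_query=aln.coverage_query,
                            evalue=ev,
                            alignment=aln,
                        )
                    )
    return _dedupe(hits)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _dedupe(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Collapse hits of one query/frame whose spans overlap reciprocally >50%."""
    hits = sorted(
        hits, key=lambda h: (h.contig, h.query_id, h.frame, -h.score, h.nuc_span)
    )
    kept: list[TranslatedHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.contig != h.contig or k.query_id != h.query_id or k.frame != h.frame:
                continue
            ov = _overlap(k.nuc_span, h.nuc_span)
            la, lb = h.nuc_span[1] - h.nuc_span[0], k.nuc_span[1] - k.nuc_span[0]
            if la and lb and ov / la > 0.5 and ov / lb > 0.5:
                redundant = True
                break
        if redundant:
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.nuc_span, h.query_id))
    return kept


def filter_hits(hits: list[TranslatedHit], cfg: MiningConfig | None = None) -> list[TranslatedHit]:
    """Keep hits with coverage and identity strictly above the thresholds."""
    cfg = cfg or MiningConfig()
    return [
        h
        for h in hits
        if h.coverage_query > cfg.min_hit_coverage and h.identity > cfg.min_hit_identity
    ]


def merge_hits_to_loci(
    hits: list[TranslatedHit], genome, cfg: MiningConfig | None = None
) -> list[CandidateLocus]:
    """Merge nearby hits (any strand) into loci and attach flanked sequence."""
    cfg = cfg or MiningConfig()
    contigs = {c.id: c for c in _as_contigs(genome)}
    for h in hits:
        if h.contig not in contigs:
            raise KeyError(f"hit references unknown contig {h.contig!r}")
    loci: list[CandidateLocus] = []
    by_contig: dict[str, list[TranslatedHit]] = {}
    for h in sorted(hits, key=lambda h: (h.contig, h.nuc_span)):
        by_contig.setdefault(h.contig, []).append(h)
    n = 0
    for contig_id, chits in by_contig.items():
        contig = contigs[contig_id]
        group: list[TranslatedHit] = []
        groups: list[list[TranslatedHit]] = []
        end = None
        for h in chits:
            if end is not None and h.nuc_span[0] - end > cfg.merge_gap_bp:
                groups.append(group)
                group = []
                end = None
            group.append(h)
            end = max(end, h.nuc_span[1]) if end is not None else h.nuc_span[1]
        if group:
            groups.append(group)
        for g in groups:
            n += 1
            core = (min(h.nuc_span[0] for h in g), max(h.nuc_span[1] for h in g))
            ext = (max(0, core[0] - cfg.flank_bp), min(len(contig), core[1] + cfg.flank_bp))
            seq = NucSequence(
                id=f"locus_{n}",
                residues=contig.residues[ext[0] : ext[1]],
                description=f"{contig_id}:{ext[0]}-{ext[1]}",
            )
            loci.append(
                CandidateLocus(
                    locus_id=f"locus_{n}",
                    contig=contig_id,
                    core_span=core,
                    extended_span=ext,
                    sequence=seq,
                    source_hits=g,
                )
            )
    return loci
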