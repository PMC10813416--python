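"""Clustering of candidate loci, TIR/TSD boundary detection, element
classification and genomic copy counting.

The protocol: candidate loci are clustered greedily at a 50% identity
threshold (longest locus is the centroid), element boundaries are found by
aligning the region upstream of the merged-hit core against the reverse
complement of the downstream region (terminal inverted repeats align with
themselves), and boundary pairs are confirmed and refined by the target
site duplication: piggyBac integration duplicates a 4-mer (canonically
TTAA) on both flanks, so the element span is the pair (i, j) whose outer
4-mers match.  Elements with both TIRs and both TSD flanks are full-length
(FL); candidates with only one TIR or one TSD are transposon-like; a copy
is *intact* if it additionally encodes a transposase of >= 500 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmer import KmerIndex
from .mine import CandidateLocus, MiningConfig
from .seqcore import (
    NucSequence,
    center_star_msa,
    majority_consensus,
    needleman_wunsch,
    reverse_complement,
    smith_waterman,
)

CANONICAL_TSD = "TTAA"


@dataclass
class Cluster:
    cluster_id: str
    centroid: CandidateLocus
    members: list[CandidateLocus] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)  # member vs centroid
    orientations: list[str] = field(default_factory=list)  # '+' as-is, '-' flipped

    @property
    def size(self) -> int:
        return len(self.members)

    def oriented_member_seq(self, i: int) -> str:
        s = self.members[i].sequence.residues
        return s if self.orientations[i] == "+" else reverse_complement(s)


@dataclass
class TirResult:
    tir_5p_span: tuple[int, int] | None
    tir_3p_span: tuple[int, int] | None
    tir_length: int
    identity: float = 0.0
    score: float = 0.0
    flush_offset: int = 0  # how far the repeat sits from hypothesized boundaries

    @property
    def found(self) -> bool:
        return self.tir_5p_span is not None and self.tir_3p_span is not None


@dataclass
class TsdResult:
    tsd: str
    left_pos: int  # element start (TSD occupies [left_pos-4, left_pos))
    right_pos: int  # element end (TSD occupies [right_pos, right_pos+4))

    @property
    def canonical(self) -> bool:
        return self.tsd == CANONICAL_TSD


@dataclass
class CopyHit:
    contig: str
    span: tuple[int, int]
    strand: str
    identity: float
    coverage: float
    score: float
    is_intact: bool = False
    tsd: str | None = None


@dataclass
class ElementModel:
    type_id: str
    boundaries: tuple[int, int] | None  # in candidate (locus) coordinates
    tir_5p_span: tuple[int, int] | None
    tir_3p_span: tuple[int, int] | None
    tir_length: int
    tsd: str | None
    tsd_canonical: bool
    consensus: NucSequence | None
    element_class: str  # FL | transposon_like | rejected
    copy_count: int = 0
    intact_copy_count: int = 0
    copy_hits: list[CopyHit] = field(default_factory=list)
    source_cluster: Cluster | None = None
    reference_index: int = 0  # member index whose (oriented) sequence holds `boundaries`
    reference_orientation: str = "+"

    def reference_locus(self):
        if self.source_cluster is None:
            return None
        return self.source_cluster.members[self.reference_index]

    def genomic_boundaries(self) -> tuple[str, int, int] | None:
        """Element span mapped back to forward-strand genome coordinates."""
        locus = self.reference_locus()
        if locus is None or self.boundaries is None:
            return None
        s, e = self.boundaries
        if self.reference_orientation == "-":
            L = len(locus.sequence)
            s, e = L - e, L - s
        off = locus.extended_span[0]
        return locus.contig, off + s, off + e


# ---------------------------------------------------------------------------
# Clustering


def _orientation_identity(a: str, b: str) -> tuple[float, str]:
    fwd = needleman_wunsch(a, b, protein=False).identity
    rev = needleman_wunsch(a, reverse_complement(b), protein=False).identity
    return (fwd, "+") if fwd >= rev else (rev, "-")


def cluster_candidates(
    loci: list[CandidateLocus], cfg: MiningConfig | None = None
) -> list[Cluster]:
    """Greedy centroid clustering at the configured identity threshold.

    Loci are taken longest-first; each joins the first centroid it matches
    at >= cluster_identity, else founds a new cluster.  Identity is the
    global-alignment identity of the merged-hit *core* regions (the 4 kb
    flanks are unrelated genomic context and would dilute any threshold),
    evaluated in both orientations.
    """
    cfg = cfg or MiningConfig()
    if not loci:
        raise ValueError("cluster_candidates requires at least one locus")
    order = sorted(loci, key=lambda l: (-len(l.sequence), l.locus_id))
    clusters: list[Cluster] = []

    def core_seq(locus: CandidateLocus) -> str:
        s, e = locus.core_in_locus
        return locus.sequence.residues[s:e]

    for locus in order:
        placed = False
        for cl in clusters:
            ident, orient = _orientation_identity(core_seq(cl.centroid), core_seq(locus))
            if ident >= cfg.cluster_identity:
                cl.members.append(locus)
                cl.identities.append(ident)
                cl.orientations.append(orient)
                placed = True
                break
        if not placed:
            cl = Cluster(
                cluster_id=f"PB-type-{len(clusters) + 1}",
                centroid=locus,
                members=[locus],
                identities=[1.0],
                orientations=["+"],
            )
            clusters.append(cl)
    return clusters


def build_msa(cluster: Cluster, max_members: int = 12) -> list[str]:
    """Center-star multiple alignment of (oriented) member sequences.

    The centroid row's ungapped length equals the centroid sequence length.
    """
    center = cluster.centroid.sequence.residues
    others = [
        cluster.oriented_member_seq(i)
        for i in range(min(cluster.size, max_members))
        if cluster.members[i] is not cluster.centroid
    ]
    return center_star_msa(center, others, protein=False)


# ---------------------------------------------------------------------------
# TIR / TSD detection


def _inverted_repeat_pairs(
    pre: str,
    post: str,
    pre_off: int,
    post_off: int,
    min_len: int,
    min_identity: float,
    n_best: int = 1,
) -> list[TirResult]:
    """Top inverted-repeat pairs between a 5' region and a 3' region.

    Successive hits are obtained by masking previous ones with N (N scores
    as a mismatch) and realigning.
    """
    results: list[TirResult] = []
    pre_l, post_l = list(pre), list(post)
    for _ in range(n_best):
        p, q = "".join(pre_l), "".join(post_l)
        if not p or not q:
            break
        aln = smith_waterman(p, reverse_complement(q), protein=False)
        if aln.is_empty:
            break
        qs, qe = aln.query_start, aln.query_end
        ss, se = aln.subject_start, aln.subject_end
        f3s, f3e = len(post) - se, len(post) - ss  # forward coords within post
        ok = aln.n_columns >= min_len and aln.identity >= min_identity
        if ok:
            results.append(
                TirResult(
                    tir_5p_span=(pre_off + qs, pre_off + qe),
                    tir_3p_span=(post_off + f3s, post_off + f3e),
                    tir_length=aln.n_columns,
                    identity=aln.identity,
                    score=aln.score,
                )
            )
        for i in range(qs, qe):
            pre_l[i] = "N"
        for i in range(f3s, f3e):
            post_l[i] = "N"
        if not ok and aln.score < min_len:  # nothing useful left
            break
    return results


def detect_tir(
    candidate_seq: str | NucSequence,
    search_window: int = 600,
    min_len: int = 4,
    min_identity: float = 0.80,
    core_span: tuple[int, int] | None = None,
    n_best: int = 1,
) -> TirResult | list[TirResult]:
    """Detect the terminal-inverted-repeat pair of a candidate element.

    The first ``search_window`` bp are aligned against the reverse
    complement of the last ``search_window`` bp; with ``core_span`` the
    windows are instead the regions flanking the core (used on loci whose
    element boundaries lie kilobases inside the candidate).  Returns the
    best pair, or a ranked list when ``n_best > 1``; absent TIRs give a
    result with ``found == False``.
    """
    seq = candidate_seq.residues if hasattr(candidate_seq, "residues") else candidate_seq
    L = len(seq)
    if L < 2 * min_len:
        empty = TirResult(None, None, 0)
        return [empty] if n_best > 1 else empty
    if core_span is None:
        w = min(search_window, L // 2)
        pre, pre_off = seq[:w], 0
        post, post_off = seq[L - w :], L - w
    else:
        cs, ce = core_span
        pre, pre_off = seq[:cs], 0
        post, post_off = seq[ce:], ce
    found = _inverted_repeat_pairs(
        pre, post, pre_off, post_off, min_len, min_identity, n_best=max(1, n_best)
    )
    if n_best > 1:
        return found
    return found[0] if found else TirResult(None, None, 0)


def detect_tsd(
    candidate_seq: str | NucSequence,
    tir_5p_span: tuple[int, int] | None,
    tir_3p_span: tuple[int, int] | None,
    slack: int = 50,
    noncanonical_flush: int = 2,
) -> TsdResult | None:
    """Find the duplicated 4-mer delimiting the element.

    Boundary pairs (i, j) are enumerated with i near the 5' TIR start and
    j near the 3' TIR end; pairs whose outer 4-mers match are ranked by
    (1) canonical TTAA first, (2) consistency with the TIR boundaries,
    (3) smallest element span.  Non-canonical 4-mers are accepted only
    flush with the TIR edges (within ``noncanonical_flush`` bp): a random
    matching 4-mer pair is far too likely inside a +/- ``slack`` window,
    whereas TTAA duplication is the integration signature itself.
    """
    seq = candidate_seq.residues if hasattr(candidate_seq, "residues") else candidate_seq
    L = len(seq)
    if tir_5p_span is None and tir_3p_span is None:
        return None
    a = tir_5p_span[0] if tir_5p_span else 4
    d = tir_3p_span[1] if tir_3p_span else L - 4
    candidates: list[tuple[tuple, TsdResult]] = []
    for i in range(max(4, a - slack), min(L - 4, a + slack) + 1):
        left = seq[i - 4 : i]
        if "N" in left:
            continue
        for j in range(max(i + 4, d - slack), min(L - 4, d + slack) + 1):
            if seq[j : j + 4] == left:
                off = abs(i - a) + abs(j - d)
                if left != CANONICAL_TSD and (
                    abs(i - a) > noncanonical_flush or abs(j - d) > noncanonical_flush
                ):
                    continue
                key = (0 if left == CANONICAL_TSD else 1, off, j - i, i)
                candidates.append((key, TsdResult(left, i, j)))
    if not candidates:
        return None
    return min(candidates, key=lambda kv: kv[0])[1]


def _flush_tir(
    seq: str,
    i: int,
    j: int,
    window: int = 600,
    min_len: int = 4,
    min_identity: float = 0.80,
    flush: int = 6,
    min_score: float = 8.0,
) -> TirResult | None:
    """Inverted-repeat pair flush with hypothesized element boundaries (i, j).

    The 5' TIR must begin within ``flush`` bp of i and the 3' TIR end
    within ``flush`` bp of j; local alignment may trim diverged terminal
    bases, which the flush tolerance absorbs.  ``min_score`` keeps chance
    4-5 bp inverted matches (common at any boundary pair) from counting
    as confirmation.
    """
    w = min(window, (j - i) // 2)
    if w < min_len:
        return None
    pre = seq[i : i + w]
    post = seq[j - w : j]
    aln = smith_waterman(pre, reverse_complement(post), protein=False)
    if aln.is_empty or aln.n_columns < min_len or aln.identity < min_identity:
        return None
    if aln.score < min_score:
        return None
    if aln.query_start > flush or aln.subject_start > flush:
        return None
    return TirResult(
        tir_5p_span=(i + aln.query_start, i + aln.query_end),
        tir_3p_span=(j - aln.subject_end, j - aln.subject_start),
        tir_length=aln.n_columns,
        identity=aln.identity,
        score=aln.score,
    )


# A boundary-flush inverted repeat must score at least this (about 8 bp of
# clean match) before it counts toward copy intactness: shorter matches
# occur by chance at a substantial rate at any hypothesized boundary pair.
INTACT_TIR_MIN_SCORE = 8.0


def _signature_tir(
    seq: str,
    i: int,
    j: int,
    min_len: int = 4,
    min_identity: float = 0.80,
    min_score: float = INTACT_TIR_MIN_SCORE,
) -> TirResult | None:
    """Terminal-signature check at element boundaries (i, j).

    The alignment windows include the 4 bp TSD context: a TTAA duplication
    is itself palindromic, so TSD+TIR forms one contiguous inverted
    repeat; scoring it jointly makes short eroded TIRs detectable exactly
    when their boundary signature is.  Reported TIR spans are clipped back
    to the element interior.
    """
    tr = _flush_tir(
        seq, max(0, i - 4), min(len(seq), j + 4),
        min_len=min_len, min_identity=min_identity, min_score=min_score,
    )
    if tr is None:
        return None
    s5, e5 = tr.tir_5p_span
    s3, e3 = tr.tir_3p_span
    flush_off = abs(s5 - max(0, i - 4)) + abs(min(len(seq), j + 4) - e3)
    clip5 = max(0, i - s5)
    clip3 = max(0, e3 - j)
    s5, e3 = s5 + clip5, e3 - clip3
    if s5 >= e5 or s3 >= e3:
        return None
    return TirResult(
        tir_5p_span=(s5, e5),
        tir_3p_span=(s3, e3),
        tir_length=max(1, tr.tir_length - clip5 - clip3),
        identity=tr.identity,
        score=tr.score,
        flush_offset=flush_off,
    )


def tir_pair_detectable(element_with_context: str, context: int = 4) -> bool:
    """Operational detectability of an element's terminal signature.

    ``element_with_context`` carries ``context`` bp of genomic flank on
    each side (the TSD); True iff the pipeline's boundary-signature rule
    fires at the known true boundaries.
    """
    L = len(element_with_context)
    return _signature_tir(element_with_context, context, L - context) is not None


def tsd_anchored_boundaries(
    seq: str,
    approx_start: int,
    approx_end: int,
    slack: int = 150,
    min_len: int = 4,
    min_identity: float = 0.80,
    max_pairs: int = 20,
) -> tuple[TsdResult, TirResult] | None:
    """Boundary search anchored on the canonical TTAA duplication.

    Candidate element spans (i, j) are TTAA...TTAA pairs near the
    approximate boundaries, closest-first; the first span confirmed by a
    flush terminal inverted repeat wins.  This is the reliable route for
    diverged elements, whose TIR arms may align worse than chance inverted
    repeats in the flanks, while the duplicated TTAA stays exact.
    """
    L = len(seq)
    lefts = [
        i
        for i in range(max(4, approx_start - slack), min(L - 4, approx_start + slack) + 1)
        if seq[i - 4 : i] == CANONICAL_TSD
    ]
    rights = [
        j
        for j in range(max(4, approx_end - slack), min(L - 4, approx_end + slack) + 1)
        if seq[j : j + 4] == CANONICAL_TSD
    ]
    pairs = sorted(
        ((i, j) for i in lefts for j in rights if j - i >= 8),
        key=lambda p: abs(p[0] - approx_start) + abs(p[1] - approx_end),
    )
    best = None
    best_key = None
    for rank, (i, j) in enumerate(pairs[:max_pairs]):
        tr = _signature_tir(seq, i, j, min_len=min_len, min_identity=min_identity)
        if tr is None:
            continue
        # a shifted boundary pair reuses the same physical repeat but sits
        # farther from it, and a TIR containing TTAA creates flush nested
        # pseudo-boundaries: prefer the flushest pair, then the strongest
        # signature (the outer, full-TIR pair), then the nearest
        key = (tr.flush_offset, -tr.score, rank)
        if best_key is None or key < best_key:
            best_key, best = key, (TsdResult(CANONICAL_TSD, i, j), tr)
    return best


# ---------------------------------------------------------------------------
# Element calling


def _dominant_band_extent(
    centroid_seq: str, member_seq: str, k: int = 12, band: int = 300
) -> tuple[int, int] | None:
    """Extent (in centroid coordinates) of the region shared with a member.

    Exact k-mer matches between the two sequences are binned by diagonal;
    the extent of the dominant band is returned.  Member flanks are
    unrelated genomic context, so the shared region approximates the
    element span.
    """
    index = KmerIndex(member_seq, k, protein=False)
    qp2, sp2 = index.lookup(centroid_seq)
    if len(qp2) < 3:
        return None
    diag = sp2 - qp2
    bins = diag // band
    vals, counts = np.unique(bins, return_counts=True)
    top = vals[int(np.argmax(counts))]
    center = int(np.median(diag[bins == top]))
    keep = np.abs(diag - center) <= band * 1.5
    if keep.sum() < 3:
        return None
    # guard against stray off-element matches: take the densest run of
    # kept seed positions (gaps <= 800 bp) as the shared extent
    qs = np.sort(qp2[keep])
    splits = np.nonzero(np.diff(qs) > 800)[0] + 1
    chunks = np.split(qs, splits)
    best = max(chunks, key=len)
    if len(best) < 3:
        return None
    return int(best.min()), int(best.max() + k)


def estimate_element_extent(cluster: Cluster) -> tuple[int, int] | None:
    """Median member-agreement extent on the centroid (None for singletons)."""
    ref = next(i for i, m in enumerate(cluster.members) if m is cluster.centroid)
    return _extent_on_reference(cluster, ref, cluster.centroid.sequence.residues)


def _trim_to_element(element: str, member_seq: str) -> str | None:
    aln = smith_waterman(element, member_seq, protein=False)
    if aln.is_empty or aln.coverage_query < 0.5:
        return None
    return member_seq[aln.subject_start : aln.subject_end]


def call_element(
    cluster: Cluster,
    cfg: MiningConfig | None = None,
    tir_min_len: int = 4,
    tir_min_identity: float = 0.80,
    tsd_slack: int = 50,
    n_tir_tries: int = 5,
) -> ElementModel:
    """Annotate one cluster: boundaries, TIR/TSD, class, consensus.

    TIR pairs are searched in the regions flanking the centroid's
    merged-hit core; each candidate pair is asked for a confirming TSD, and
    the first TIR pair with a TSD wins (candidate pairs are score-ranked).
    """
    cfg = cfg or MiningConfig()
    centroid = cluster.centroid

    # Candidate annotation references: centroid first, then other members
    # longest-first.  A degraded reference copy (e.g. one TIR deleted) can
    # never anchor boundaries; a sibling copy usually can.
    order = [i for i, m in enumerate(cluster.members) if m is centroid]
    order += sorted(
        (i for i, m in enumerate(cluster.members) if m is not centroid),
        key=lambda i: (-len(cluster.members[i].sequence), cluster.members[i].locus_id),
    )

    # TSD-first anchoring: the member-agreement extent localizes the
    # element (clustered copies share only the element, not their flanks),
    # then TTAA-duplication pairs near the extent edges are confirmed by a
    # flush terminal inverted repeat.
    for idx in order[:3]:
        seq_i = (
            centroid.sequence.residues
            if cluster.members[idx] is centroid
            else cluster.oriented_member_seq(idx)
        )
        extent = _extent_on_reference(cluster, idx, seq_i)
        if extent is None:
            continue
        anchored = tsd_anchored_boundaries(
            seq_i, extent[0], extent[1],
            min_len=tir_min_len, min_identity=tir_min_identity,
        )
        if anchored is not None:
            ts, tr = anchored
            return _finalize_element(cluster, seq_i, tr, ts, cfg, reference=idx)

    # Fallback: inverted-repeat-first on the centroid, TSD as confirmation.
    seq = centroid.sequence.residues
    core = centroid.core_in_locus
    extent = _extent_on_reference(cluster, order[0], seq)
    if extent is not None:
        margin = 250
        s_lo = max(0, extent[0] - margin)
        s_hi = min(core[0], extent[0] + margin)
        e_lo = max(core[1], extent[1] - margin)
        e_hi = min(len(seq), extent[1] + margin)
        tir_candidates = _inverted_repeat_pairs(
            seq[s_lo:s_hi], seq[e_lo:e_hi], s_lo, e_lo,
            tir_min_len, tir_min_identity, n_best=n_tir_tries,
        )
    else:
        tir_candidates = detect_tir(
            seq,
            min_len=tir_min_len,
            min_identity=tir_min_identity,
            core_span=core,
            n_best=n_tir_tries,
        )
    best_tir: TirResult | None = None
    best_tsd: TsdResult | None = None
    for tr in tir_candidates:
        if not tr.found:
            continue
        ts = detect_tsd(seq, tr.tir_5p_span, tr.tir_3p_span, slack=tsd_slack)
        # a non-TTAA duplication needs a strong confirming repeat: chance
        # matching 4-mers flush with weak inverted repeats are common
        if ts is not None and not ts.canonical and tr.score < 12:
            ts = None
        # any accepted boundary pair must carry the terminal signature
        if ts is not None and _signature_tir(seq, ts.left_pos, ts.right_pos) is None:
            ts = None
        if ts is not None:
            best_tir, best_tsd = tr, ts
            break
        if best_tir is None:
            best_tir = tr

    return _finalize_element(cluster, seq, best_tir, best_tsd, cfg, reference=order[0])


def _extent_on_reference(
    cluster: Cluster, ref_idx: int, ref_seq: str
) -> tuple[int, int] | None:
    """Median member-agreement extent on one reference member."""
    starts, ends = [], []
    used = 0
    for i in range(cluster.size):
        if i == ref_idx or used >= 4:
            continue
        ext = _dominant_band_extent(ref_seq, cluster.oriented_member_seq(i))
        if ext:
            starts.append(ext[0])
            ends.append(ext[1])
            used += 1
    if not starts:
        return None
    return int(np.median(starts)), int(np.median(ends))


def _finalize_element(
    cluster: Cluster,
    seq: str,
    best_tir: TirResult | None,
    best_tsd: TsdResult | None,
    cfg: MiningConfig,
    reference: int = 0,
) -> ElementModel:
    centroid = cluster.centroid
    n_tirs = 2 if (best_tir and best_tir.found) else 0
    if best_tsd is not None:
        boundaries = (best_tsd.left_pos, best_tsd.right_pos)
        n_tsds = 2
    elif best_tir is not None:
        boundaries = (best_tir.tir_5p_span[0], best_tir.tir_3p_span[1])
        left = seq[boundaries[0] - 4 : boundaries[0]]
        right = seq[boundaries[1] : boundaries[1] + 4]
        n_tsds = int(left == CANONICAL_TSD) + int(right == CANONICAL_TSD)
        if n_tsds == 2:  # unequal 4-mers would have been caught by detect_tsd
            n_tsds = 1
    else:
        boundaries = None
        n_tsds = 0

    if n_tirs == 2 and n_tsds == 2:
        element_class = "FL"
    elif n_tirs >= 1 or n_tsds >= 1:
        element_class = "transposon_like"
    else:
        element_class = "rejected"

    consensus = None
    if boundaries is not None:
        element = seq[boundaries[0] : boundaries[1]]
        trimmed = []
        for i in range(min(cluster.size, 8)):
            if cluster.members[i] is centroid:
                continue
            t = _trim_to_element(element, cluster.oriented_member_seq(i))
            if t:
                trimmed.append(t)
        if trimmed:
            rows = center_star_msa(element, trimmed, protein=False)
            cons = majority_consensus(rows)
        else:
            cons = element
        consensus = NucSequence(cluster.cluster_id, cons)

    return ElementModel(
        type_id=cluster.cluster_id,
        boundaries=boundaries,
        tir_5p_span=best_tir.tir_5p_span if best_tir else None,
        tir_3p_span=best_tir.tir_3p_span if best_tir else None,
        tir_length=best_tir.tir_length if best_tir else 0,
        tsd=best_tsd.tsd if best_tsd else None,
        tsd_canonical=best_tsd.canonical if best_tsd else False,
        consensus=consensus,
        element_class=element_class,
        source_cluster=cluster,
        reference_index=reference,
        reference_orientation=cluster.orientations[reference],
    )


# ---------------------------------------------------------------------------
# Copy counting


def _seed_regions(
    index: KmerIndex,
    query: str,
    k: int,
    min_seeds: int,
    limit: int,
    diag_slack: int = 100,
    pos_gap: int = 3000,
    pad: int = 150,
) -> list[tuple[int, int]]:
    """Candidate genomic windows from diagonal-banded exact k-mer seeds.

    Each band's window is widened by the unseeded query overhangs so a
    local alignment can cover the whole copy; overlapping windows merge.
    """
    qp, sp = index.lookup(query)
    if len(sp) < min_seeds:
        return []
    diag = sp - qp
    order = np.lexsort((sp, diag))
    d_s, s_s, q_s = diag[order], sp[order], qp[order]
    brk = np.nonzero((np.diff(d_s) > diag_slack) | (np.abs(np.diff(s_s)) > pos_gap))[0] + 1
    windows = []
    for chunk in np.split(np.arange(len(order)), brk):
        if len(chunk) < min_seeds:
            continue
        smin, smax = int(s_s[chunk].min()), int(s_s[chunk].max()) + k
        qmin, qmax = int(q_s[chunk].min()), int(q_s[chunk].max()) + k
        lo = max(0, smin - qmin - pad)
        hi = min(limit, smax + (len(query) - qmax) + pad)
        windows.append((lo, hi))
    windows.sort()
    merged: list[list[int]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def count_copies(
    genome,
    element: ElementModel,
    cfg: MiningConfig | None = None,
    index_cache: dict | None = None,
) -> tuple[int, list[CopyHit]]:
    """BLASTN-like scan of the consensus against the genome (both strands).

    Hits overlapping >50% reciprocally are collapsed to the best score;
    hits are retained with coverage > copy_min_coverage and identity >
    copy_min_identity (strict, matching the protocol's "over").
    """
    cfg = cfg or MiningConfig()
    if element.consensus is None:
        return 0, []
    consensus = element.consensus.residues
    contigs = (
        [genome] if isinstance(genome, NucSequence) else list(genome)
    )
    hits: list[CopyHit] = []
    for contig in contigs:
        if index_cache is not None and contig.id in index_cache:
            index = index_cache[contig.id]
        else:
            index = KmerIndex(contig.residues, cfg.copy_seed_k, protein=False)
            if index_cache is not None:
                index_cache[contig.id] = index
        for strand, q in (("+", consensus), ("-", reverse_complement(consensus))):
            for s, e in _seed_regions(
                index, q, cfg.copy_seed_k, cfg.copy_min_seeds, len(contig)
            ):
                hit = _window_hit(q, contig.residues[s:e], s, contig.id, strand, cfg)
                if hit is not None:
                    hits.append(hit)
    hits = _collapse_hits(hits)
    hits = [
        h
        for h in hits
        if h.coverage > cfg.copy_min_coverage and h.identity > cfg.copy_min_identity
    ]
    hits.sort(key=lambda h: (h.contig, h.span))
    return len(hits), hits


def _window_hit(
    query: str,
    window: str,
    offset: int,
    contig_id: str,
    strand: str,
    cfg: MiningConfig,
    max_hsps: int = 3,
) -> CopyHit | None:
    """One copy hit from a candidate window, chaining co-linear HSPs.

    A copy with a large internal deletion aligns as two local segments
    (the affine gap cost forbids bridging); like a BLAST multi-HSP hit,
    co-linear segments are combined so query coverage reflects the whole
    copy.  Coverage is the union of aligned query spans over the query
    length; identity is the column-weighted mean.
    """
    work = list(window)
    hsps = []
    for _ in range(max_hsps):
        aln = smith_waterman(query, "".join(work), protein=False)
        if aln.is_empty or aln.score < 3 * cfg.copy_seed_k:
            break
        hsps.append(aln)
        for i in range(aln.subject_start, aln.subject_end):
            work[i] = "N"
        if sum(a.query_end - a.query_start for a in hsps) >= 0.95 * len(query):
            break
    if not hsps:
        return None
    best = hsps[0]
    chain = [best]
    for aln in hsps[1:]:
        ok = True
        for c in chain:
            same_order = (aln.query_start >= c.query_end) == (
                aln.subject_start >= c.subject_end
            )
            q_ov = min(aln.query_end, c.query_end) - max(aln.query_start, c.query_start)
            if not same_order or q_ov > 0.5 * (aln.query_end - aln.query_start):
                ok = False
                break
        if ok:
            chain.append(aln)
    qspans = sorted((a.query_start, a.query_end) for a in chain)
    covered = 0
    last = -1
    for qs, qe in qspans:
        covered += max(0, qe - max(qs, last))
        last = max(last, qe)
    ncols = sum(a.n_columns for a in chain)
    ident = sum(a.identity * a.n_columns for a in chain) / ncols
    span = (
        offset + min(a.subject_start for a in chain),
        offset + max(a.subject_end for a in chain),
    )
    return CopyHit(
        contig=contig_id,
        span=span,
        strand=strand,
        identity=ident,
        coverage=covered / len(query),
        score=sum(a.score for a in chain),
    )


def _collapse_hits(hits: list[CopyHit]) -> list[CopyHit]:
    hits = sorted(hits, key=lambda h: (-h.score, h.contig, h.span))
    kept: list[CopyHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if k.contig != h.contig:
                continue
            ov = max(0, min(k.span[1], h.span[1]) - max(k.span[0], h.span[0]))
            la, lb = h.span[1] - h.span[0], k.span[1] - k.span[0]
            if la and lb and ov / la > 0.5 and ov / lb > 0.5:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


@dataclass
class CopyAnnotation:
    """Structural annotation of one genomic copy on its own flanks."""

    tir_found: bool
    tsd: str | None
    refined_span: tuple[int, int] | None  # TSD-anchored element span, genome coords
    longest_orf_aa: int
    is_intact: bool


def annotate_copy(
    copy_hit: CopyHit,
    genome,
    cfg: MiningConfig | None = None,
    flank: int = 120,
    tir_min_len: int = 4,
    tir_min_identity: float = 0.80,
    expected_tsd: str | None = None,
) -> CopyAnnotation:
    """TIR/TSD/ORF annotation of a single copy.

    A copy is intact iff one consistent boundary pair carries both a
    detectable TIR pair (flush, score >= INTACT_TIR_MIN_SCORE) and a TSD
    pair, AND its longest ORF encodes >= 500 aa (inclusive bound).  With
    ``expected_tsd`` (the family's TSD), a copy whose TSD disagrees is not
    intact — chance 4-mer pairs at spurious boundaries fail this check.
    When a TSD anchors boundaries, the refined element span replaces the
    raw alignment span for downstream reporting.
    """
    from .transposase import find_orfs  # local import to avoid a cycle

    cfg = cfg or MiningConfig()
    contigs = {c.id: c for c in ([genome] if isinstance(genome, NucSequence) else genome)}
    contig = contigs[copy_hit.contig]
    s, e = copy_hit.span
    ws, we = max(0, s - flank), min(len(contig), e + flank)
    sub = contig.residues[ws:we]
    tir_found = False
    struct_ok = False
    tsd: TsdResult | None = None
    anchored = tsd_anchored_boundaries(
        sub, s - ws, e - ws, slack=60,
        min_len=tir_min_len, min_identity=tir_min_identity,
    )
    if anchored is not None:
        tsd, _tr = anchored
        tir_found = True
        struct_ok = expected_tsd is None or tsd.tsd == expected_tsd
    else:
        tirs = detect_tir(
            sub,
            search_window=flank + 650,
            min_len=tir_min_len,
            min_identity=tir_min_identity,
            n_best=3,
        )
        for tr in tirs:
            if not tr.found:
                continue
            if tr.score >= INTACT_TIR_MIN_SCORE:
                tir_found = True
            # tight slack: a loose window would let a chance TTAA near the
            # TIR edge rescue copies that genuinely lack one duplication
            ts = detect_tsd(sub, tr.tir_5p_span, tr.tir_3p_span, slack=5)
            if ts is not None:
                # boundaries must agree with the copy-alignment span: a TSD
                # pair that truncates the aligned copy is a chance match
                if abs(ts.left_pos - (s - ws)) > 60 or abs(ts.right_pos - (e - ws)) > 60:
                    continue
                tsd = ts
                sig = _signature_tir(sub, ts.left_pos, ts.right_pos)
                struct_ok = sig is not None and (
                    expected_tsd is None or ts.tsd == expected_tsd
                )
                break
    refined = None
    if tsd is not None:
        refined = (ws + tsd.left_pos, ws + tsd.right_pos)
    _, longest = find_orfs(sub)
    orf_aa = longest.length_aa if longest else 0
    return CopyAnnotation(
        tir_found=tir_found,
        tsd=tsd.tsd if tsd else None,
        refined_span=refined,
        longest_orf_aa=orf_aa,
        is_intact=struct_ok and orf_aa >= cfg.intact_min_transposase_aa,
    )


def classify_intact(copy_hit: CopyHit, genome, cfg: MiningConfig | None = None, **kw) -> bool:
    """True iff the copy has a detectable TIR pair and TSD pair on its own
    flanks AND its longest ORF encodes >= 500 aa (inclusive bound)."""
    return annotate_copy(copy_hit, genome, cfg, **kw).is_intact
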