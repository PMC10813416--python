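"""Foundational sequence types, translation and pairwise alignment.

Everything downstream (mining, boundary detection, phylogeny, divergence)
is built on the primitives here: validated nucleotide/protein sequences,
six-frame translation with coordinate back-mapping, local and global
pairwise alignment with BLAST-like scoring, Karlin-Altschul E-values, and
FASTA I/O.

Coordinates are 0-based, half-open throughout the package; 1-based
coordinates appear only in exported GFF3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# BLAST-convention gap penalties: a gap of length k costs open + k * extend.
PROTEIN_GAP_OPEN = 11
PROTEIN_GAP_EXTEND = 1
NUC_MATCH = 1
NUC_MISMATCH = -2
NUC_GAP_OPEN = 5
NUC_GAP_EXTEND = 2

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap costs 11/1.
KA_K = 0.041
KA_LAMBDA = 0.267


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass(frozen=True)
class NucSequence:
    """A DNA sequence over {A, C, G, T, N}; lowercase input is normalized."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProtSequence:
    """A protein sequence over the 20 amino acids plus X; '*' only terminal."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - PROT_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"protein {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if "*" in self.residues[:-1]:
            raise InvalidSequenceError(
                f"protein {self.id!r} has an internal stop; '*' is terminal only"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentResult:
    """A pairwise alignment with BLAST-style summary statistics.

    ``identity`` counts identical columns over *all* alignment columns
    (gap columns included); ``coverage_query`` is the aligned fraction of
    the query.  ``evalue`` is populated for local protein alignments only.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str
    score: float
    identity: float
    coverage_query: float
    evalue: float | None = None

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def reverse_complement(seq: NucSequence | str) -> NucSequence | str:
    """Watson-Crick reverse complement; N maps to N. Accepts str or NucSequence."""
    if isinstance(seq, str):
        bad = set(seq.upper()) - NUC_ALPHABET
        if bad:
            raise InvalidSequenceError(f"non-IUPAC characters: {sorted(bad)}")
        return seq.upper().translate(_COMPLEMENT)[::-1]
    return NucSequence(
        id=seq.id,
        residues=seq.residues.translate(_COMPLEMENT)[::-1],
        description=seq.description,
    )


@dataclass(frozen=True)
class FrameTranslation:
    """One reading-frame translation with the metadata to map coordinates back."""

    frame: int  # +1, +2, +3, -1, -2, -3
    protein: ProtSequence
    source_length: int

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def nuc_span(self, prot_start: int, prot_end: int) -> tuple[int, int]:
        """Map a protein span (half-open) back to forward-strand nucleotides."""
        s = self.offset + 3 * prot_start
        e = self.offset + 3 * prot_end
        if self.frame > 0:
            return s, e
        return self.source_length - e, self.source_length - s


def _translate_str(nuc: str) -> str:
    usable = len(nuc) - len(nuc) % 3
    return str(Seq(nuc[:usable]).translate(table=1))


def six_frame_translate(seq: NucSequence) -> list[FrameTranslation]:
    """Translate all six reading frames under the standard genetic code.

    Stops are rendered ``*`` (internal stops are kept, so the raw frame
    strings are plain str, not ProtSequence-validated chains).
    """
    if len(seq) < 3:
        raise InvalidSequenceError(f"sequence {seq.id!r} shorter than one codon")
    out: list[FrameTranslation] = []
    rc = reverse_complement(seq).residues
    for strand, residues in ((1, seq.residues), (-1, rc)):
        for off in range(3):
            if len(residues) - off < 3:
                continue
            aa = _translate_str(residues[off:])
            frame = strand * (off + 1)
            prot = ProtSequence.__new__(ProtSequence)
            object.__setattr__(prot, "id", f"{seq.id}|frame{frame:+d}")
            object.__setattr__(prot, "residues", aa)
            object.__setattr__(prot, "description", "")
            out.append(FrameTranslation(frame=frame, protein=prot, source_length=len(seq)))
    return out


@lru_cache(maxsize=None)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def _nuc_matrix(match: int = NUC_MATCH, mismatch: int = NUC_MISMATCH):
    # N scores as a mismatch against everything, including N.
    alpha = "ACGTN"
    m = substitution_matrices.Array(alphabet=alpha, dims=2)
    for x in alpha:
        for y in alpha:
            if x == y and x != "N":
                m[x, y] = match
            else:
                m[x, y] = mismatch
    return m


def _make_aligner(protein: bool, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if protein:
        al.substitution_matrix = _blosum62()
        al.open_gap_score = -(PROTEIN_GAP_OPEN + PROTEIN_GAP_EXTEND)
        al.extend_gap_score = -PROTEIN_GAP_EXTEND
    else:
        al.substitution_matrix = _nuc_matrix()
        al.open_gap_score = -(NUC_GAP_OPEN + NUC_GAP_EXTEND)
        al.extend_gap_score = -NUC_GAP_EXTEND
    return al


def _residues(x) -> str:
    return x.residues if hasattr(x, "residues") else str(x).upper()


def _seq_id(x, default: str) -> str:
    return x.id if hasattr(x, "id") else default


def _is_protein(a: str, b: str, protein: bool | None) -> bool:
    if protein is not None:
        return protein
    return not (set(a) <= NUC_ALPHABET and set(b) <= NUC_ALPHABET)


def _summarize(aln, query: str, subject: str, qid: str, sid: str) -> AlignmentResult:
    gq, gs = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    qs, qe = int(coords[0][0]), int(coords[0][-1])
    ss, se = int(coords[1][0]), int(coords[1][-1])
    ncol = len(gq)
    matches = sum(1 for x, y in zip(gq, gs) if x == y and x != "-")
    identity = matches / ncol if ncol else 0.0
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        aligned_query=gq,
        aligned_subject=gs,
        score=float(aln.score),
        identity=identity,
        coverage_query=(qe - qs) / len(query) if query else 0.0,
    )


def _empty_result(qid: str, sid: str) -> AlignmentResult:
    return AlignmentResult(qid, sid, 0, 0, 0, 0, "", "", 0.0, 0.0, 0.0)


def smith_waterman(a, b, protein: bool | None = None) -> AlignmentResult:
    """Maximal-scoring local alignment of ``a`` (query) vs ``b`` (subject).

    Protein scoring is BLOSUM62 with gap costs 11/1; nucleotide scoring is
    +1/-2 with gap costs 5/2 (BLAST-like defaults).  When both inputs fit
    the DNA alphabet they are aligned as DNA unless ``protein=True``.
    """
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise InvalidSequenceError("cannot align empty sequences")
    aligner = _make_aligner(_is_protein(ra, rb, protein), "local")
    alns = aligner.align(ra, rb)
    try:
        best = alns[0]
    except IndexError:
        return _empty_result(_seq_id(a, "query"), _seq_id(b, "subject"))
    if best.score <= 0:
        return _empty_result(_seq_id(a, "query"), _seq_id(b, "subject"))
    return _summarize(best, ra, rb, _seq_id(a, "query"), _seq_id(b, "subject"))


def needleman_wunsch(a, b, protein: bool | None = None) -> AlignmentResult:
    """End-to-end global alignment with the same scoring as smith_waterman."""
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise InvalidSequenceError("cannot align empty sequences")
    aligner = _make_aligner(_is_protein(ra, rb, protein), "global")
    best = aligner.align(ra, rb)[0]
    return _summarize(best, ra, rb, _seq_id(a, "query"), _seq_id(b, "subject"))


def global_identity(a, b, protein: bool | None = None) -> float:
    """Identity (identical columns / all columns) of the global alignment."""
    return needleman_wunsch(a, b, protein=protein).identity


def karlin_altschul_evalue(
    score: float, m: int, n: int, K: float = KA_K, lam: float = KA_LAMBDA
) -> float:
    """Karlin-Altschul expected number of chance hits: E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search space dimensions must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return K * m * n * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# FASTA I/O (wrapped at 60 columns on write, lowercase tolerated on read)


def read_fasta(path: str | Path, protein: bool = False) -> list[NucSequence] | list[ProtSequence]:
    cls = ProtSequence if protein else NucSequence
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(cls(id=rec.id, residues=str(rec.seq), description=desc))
    return out


def write_fasta(path: str | Path, seqs: Iterable[NucSequence | ProtSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Center-star multiple alignment (shared by boundary consensus and phylogeny)


def center_star_msa(
    center: str, others: Sequence[str], protein: bool | None = None
) -> list[str]:
    """Center-star MSA: project pairwise global alignments onto the center.

    Returns gapped rows ``[center_row, *other_rows]`` of equal length.  The
    center row's ungapped length always equals ``len(center)``; insertions
    relative to the center open new columns merged across members.
    """
    if not others:
        return [center]
    pairwise = [needleman_wunsch(center, o, protein=protein) for o in others]
    # extra columns inserted after each center position (index 0..len(center))
    n = len(center)
    extra = [0] * (n + 1)
    per_member: list[list[tuple[int, str]]] = []
    for res in pairwise:
        cpos = 0
        run = 0
        cols: list[tuple[int, str]] = []  # (center_pos_or_insert_slot, member_char)
        for cch, och in zip(res.aligned_query, res.aligned_subject):
            if cch == "-":
                run += 1
                cols.append((-cpos - 1, och))  # insertion before center pos cpos
            else:
                extra[cpos] = max(extra[cpos], run)
                run = 0
                cols.append((cpos, och))
                cpos += 1
        extra[n] = max(extra[n], run)
        per_member.append(cols)
    # recompute trailing-run maxima correctly: runs were flushed on next match
    for cols in per_member:
        run = 0
        for slot, _ in cols:
            if slot < 0:
                run += 1
            else:
                extra[slot] = max(extra[slot], run)
                run = 0
        extra[n] = max(extra[n], run)

    # column layout: for center pos i, `extra[i]` insert columns precede it
    col_of_center = [0] * n
    c = 0
    for i in range(n):
        c += extra[i]
        col_of_center[i] = c
        c += 1
    total_cols = c + extra[n]

    rows = []
    center_row = ["-"] * total_cols
    for i, ch in enumerate(center):
        center_row[col_of_center[i]] = ch
    rows.append("".join(center_row))

    for cols in per_member:
        row = ["-"] * total_cols
        ins_run = 0
        for slot, ch in cols:
            if slot < 0:
                cpos = -slot - 1
                base = (col_of_center[cpos] - extra[cpos]) if cpos < n else (
                    total_cols - extra[n]
                )
                row[base + ins_run] = ch
                ins_run += 1
            else:
                row[col_of_center[slot]] = ch
                ins_run = 0
        rows.append("".join(row))
    return rows


def majority_consensus(rows: Sequence[str], ignore_gaps: bool = False) -> str:
    """Column-wise majority consensus of equal-length gapped rows.

    Columns whose majority character is a gap are dropped (so insertions
    private to a minority of members do not enter the consensus).  Ties
    break alphabetically for determinism; '-' sorts first, so a gap tie
    drops the column.
    """
    if not rows:
        return ""
    ncol = len(rows[0])
    out = []
    for j in range(ncol):
        counts: dict[str, int] = {}
        for r in rows:
            counts[r[j]] = counts.get(r[j], 0) + 1
        if ignore_gaps and len(counts) > 1:
            nongap = {k: v for k, v in counts.items() if k != "-"}
            if nongap:
                counts = nongap
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if best != "-":
            out.append(best)
    return "".join(out)
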