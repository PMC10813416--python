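"""Synthetic genomes with planted piggyBac-like transposon families.

The generator emulates the structural hallmarks of piggyBac elements: short
terminal inverted repeats (TIRs, 4-600 bp) whose 5' ends carry one of the
conserved CACTA/CCCTC/CCCTT/CCCAT motifs, integration at TTAA tetramers
with target-site duplication (TSD) on both flanks, a single transposase ORF
(>= 500 aa by default) with a DDD catalytic triad at family-typical
spacings and a C-terminal cysteine-rich domain (CRD) of eight cysteines,
per-copy divergence under the Kimura 2-parameter substitution process, and
a configurable fraction of truncated or degenerate copies.

Ground truth (every planted copy with its realized span, strand, target
divergence and integrity) is recorded so the mining/annotation pipeline can
be scored by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .seqcore import NucSequence, ProtSequence, reverse_complement, write_fasta

TIR_MOTIFS = ("CACTA", "CCCTC", "CCCTT", "CCCAT")
DEGRADE_MODES = ("missing_tir", "missing_tsd", "internal_deletion", "orf_disrupted")

# observed element / transposase envelopes the templates are drawn from
FULL_LENGTH_RANGE = (1230, 9510)
TRANSPOSASE_AA_RANGE = (503, 1316)
D1_D2_RANGE = (78, 85)
D2_D3_RANGE = (98, 113)

_STOP_CODONS = ("TAA", "TAG", "TGA")

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

# background amino-acid pool for template transposases: D and C are reserved
# for the designed catalytic triad and CRD so domain recovery is unambiguous
_BG_AA = "AEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TransposonTemplate:
    """Ground-truth design of one transposon family."""

    type_id: str
    tir_5p: str
    tir_3p: str
    tsd: str
    cds: str
    full_sequence: str
    transposase: str
    ddd_positions: tuple[int, int, int]
    crd_cys_positions: tuple[int, ...]
    cds_span: tuple[int, int]  # half-open, element coordinates
    tir_length: int

    def as_nuc(self) -> NucSequence:
        return NucSequence(self.type_id, self.full_sequence)

    def transposase_prot(self) -> ProtSequence:
        return ProtSequence(f"{self.type_id}_tpase", self.transposase)


@dataclass
class PlantedCopy:
    """One realized insertion in the simulated genome."""

    type_id: str
    copy_index: int
    contig: str
    strand: str
    target_divergence: float
    integrity: str  # intact | missing_tir | missing_tsd | internal_deletion | orf_disrupted
    realized_span: tuple[int, int]  # half-open in the final genome
    is_intact: bool
    tsd: str


@dataclass
class SimConfig:
    """Study conditions for one simulated genome."""

    genome_length: int = 2_000_000
    gc_fraction: float = 0.40
    n_types: int = 12
    copies_per_type: int | tuple[int, int] | list[int] = (4, 8)
    divergence_grid: tuple[float, ...] = (0.0, 0.02, 0.05, 0.10)
    kappa: float = 2.0
    truncation_fraction: float = 0.20
    seed: int = 0
    tsd: str = "TTAA"
    min_spacing_bp: int = 12_000
    tir_length_range: tuple[int, int] = (12, 24)
    transposase_aa_range: tuple[int, int] = (503, 675)
    contig_name: str = "chr1"

    def validate(self) -> None:
        for name in ("gc_fraction", "truncation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if len(self.tsd) != 4:
            raise ValueError("TSD must be 4 bp")


def _random_nuc(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def build_template(
    rng: np.random.Generator,
    type_id: str = "PB-sim-1",
    tir_length: int = 14,
    tir_motif: str = "CCCTT",
    transposase_len: int | None = None,
    transposase_aa_range: tuple[int, int] = (503, 675),
    tsd: str = "TTAA",
    d1_d2: int | None = None,
    d2_d3: int | None = None,
    spacer_range: tuple[int, int] = (80, 300),
    allow_short: bool = False,
) -> TransposonTemplate:
    """Design one transposon family with known internal anatomy.

    The transposase is drawn from a background pool excluding D and C, then
    the catalytic aspartates and the eight CRD cysteines are written in at
    their designed positions, so the locators can be scored exactly.
    """
    if not 4 <= tir_length <= 600:
        raise ValueError(f"TIR length {tir_length} outside [4, 600]")
    if transposase_len is None:
        lo, hi = transposase_aa_range
        transposase_len = int(rng.integers(lo, hi + 1))
    if transposase_len < 54 or (transposase_len < 500 and not allow_short):
        raise ValueError(
            f"transposase length {transposase_len} below design minimum "
            "(pass allow_short=True for degenerate templates)"
        )
    L = transposase_len
    d1_d2 = int(rng.integers(*D1_D2_RANGE)) if d1_d2 is None else d1_d2
    d2_d3 = int(rng.integers(*D2_D3_RANGE)) if d2_d3 is None else d2_d3

    aa = list(rng.choice(list(_BG_AA), size=L))
    aa[0] = "M"
    # catalytic triad roughly centered; CRD occupies the C-terminal window
    crd_window = 120
    crd_needed = L >= 500 or L >= 300
    d1_min, d1_max = 120, L - d1_d2 - d2_d3 - (crd_window + 20)
    if d1_max <= d1_min:
        if L < 54 + d1_d2 + d2_d3:
            raise ValueError("transposase too short for requested triad spacings")
        d1_min, d1_max = 10, L - d1_d2 - d2_d3 - 10
        crd_needed = False
    d1 = int(rng.integers(d1_min, d1_max))
    d2, d3 = d1 + d1_d2, d1 + d1_d2 + d2_d3
    for d in (d1, d2, d3):
        aa[d] = "D"
    crd_positions: tuple[int, ...] = ()
    if crd_needed:
        start = L - crd_window + 5
        step = (crd_window - 20) // 8
        crd_positions = tuple(start + i * step for i in range(8))
        for c in crd_positions:
            aa[c] = "C"
    protein = "".join(aa)

    if len(tir_motif) > tir_length:
        tir_motif = tir_motif[:tir_length]
    tir_5p = (tir_motif + _random_nuc(rng, max(0, tir_length - len(tir_motif))))[
        :tir_length
    ]
    tir_3p = reverse_complement(tir_5p)

    # the spacer ends with an in-frame stop so no upstream ATG can extend
    # the designed ORF beyond its intended start
    spacer5 = _random_nuc(rng, int(rng.integers(*spacer_range))) + "TAA"
    spacer3 = _random_nuc(rng, int(rng.integers(*spacer_range)))

    # resample codons until the designed CDS is the unique long ORF: a
    # chance stop-free stretch in a shifted frame would defeat the
    # orf-disruption degradation mode and the intactness ground truth
    from .transposase import find_orfs

    for _ in range(25):
        codon_choices = [
            _CODONS_BY_AA[a][int(rng.integers(len(_CODONS_BY_AA[a])))] for a in protein
        ]
        cds = "".join(codon_choices) + _STOP_CODONS[int(rng.integers(3))]
        full = tir_5p + spacer5 + cds + spacer3 + tir_3p
        cds_start = tir_length + len(spacer5)
        designed_span = (cds_start, cds_start + len(cds))
        calls, _ = find_orfs(full, min_aa=100)
        fr = cds_start % 3 + 1
        rivals = [
            o.length_aa
            for o in calls
            # nested starts inside the designed CDS share its stop and are
            # killed by the same disruptions; only other frames/strands rival
            if not (
                o.strand == "+"
                and o.frame == fr
                and designed_span[0] <= o.nuc_span[0]
                and o.nuc_span[1] <= designed_span[1]
            )
        ]
        if not rivals or max(rivals) < min(450, max(150, L - 20)):
            break
    else:
        raise ValueError("could not design a template with a unique long ORF")
    if not FULL_LENGTH_RANGE[0] <= len(full) <= FULL_LENGTH_RANGE[1] and not allow_short:
        raise ValueError(
            f"designed element length {len(full)} outside {FULL_LENGTH_RANGE}"
        )
    cds_start = tir_length + len(spacer5)
    return TransposonTemplate(
        type_id=type_id,
        tir_5p=tir_5p,
        tir_3p=tir_3p,
        tsd=tsd,
        cds=cds,
        full_sequence=full,
        transposase=protein,
        ddd_positions=(d1, d2, d3),
        crd_cys_positions=crd_positions,
        cds_span=(cds_start, cds_start + len(cds)),
        tir_length=tir_length,
    )


# ---------------------------------------------------------------------------
# Kimura 2-parameter forward evolution

def _k2p_site_probs(target_k: float, kappa: float) -> tuple[float, float]:
    """Per-site (transition, per-class transversion) substitution probabilities
    of the K2P process run to expected distance ``target_k``."""
    bt = target_k / (kappa + 2)  # beta * t
    at = kappa * bt  # alpha * t
    p_ts = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
    p_tv = 0.25 - 0.25 * math.exp(-4 * bt)  # each of the two transversion targets
    return p_ts, p_tv


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


def evolve_copy(
    sequence: str,
    target_k: float,
    kappa: float,
    rng: np.random.Generator,
    preserve_orf_span: tuple[int, int] | None = None,
) -> str:
    """Substitute per site under the Kimura 2-parameter model.

    The per-site substitution probabilities are the exact K2P transition
    probabilities at divergence ``target_k`` with transition/transversion
    rate ratio ``kappa``, so the expected K2P distance of the output to the
    input equals ``target_k``.

    With ``preserve_orf_span`` (half-open element coordinates of a CDS on
    the forward strand), substitutions that would create a premature stop
    codon are reverted — a purifying-selection emulation used for copies
    planted as intact.
    """
    if target_k < 0:
        raise ValueError("target divergence must be nonnegative")
    if target_k > 0.75:
        raise ValueError(f"target divergence {target_k} beyond saturation guard 0.75")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if target_k == 0:
        return sequence
    p_ts, p_tv = _k2p_site_probs(target_k, kappa)
    n = len(sequence)
    u = rng.random(n)
    pick = rng.random(n)
    out = list(sequence)
    changed: list[int] = []
    for i, base in enumerate(sequence):
        if base not in _TS_PARTNER:
            continue
        if u[i] < p_ts:
            out[i] = _TS_PARTNER[base]
            changed.append(i)
        elif u[i] < p_ts + 2 * p_tv:
            out[i] = _TV_PARTNERS[base][0 if pick[i] < 0.5 else 1]
            changed.append(i)
    if preserve_orf_span is not None and changed:
        s, e = preserve_orf_span
        # the CDS terminal stop codon is exempt
        coding_end = e - 3
        for i in changed:
            if not s <= i < coding_end:
                continue
            if i < s + 3:  # keep the ATG start
                out[i] = sequence[i]
                continue
            codon_i = s + 3 * ((i - s) // 3)
            if "".join(out[codon_i : codon_i + 3]) in _STOP_CODONS:
                out[i] = sequence[i]
    return "".join(out)


def degrade_copy(
    sequence: str,
    template: TransposonTemplate,
    mode: str,
    rng: np.random.Generator,
) -> str:
    """Apply one discrete truncation/degeneration mode to an element copy.

    ``missing_tsd`` leaves the sequence untouched; the duplication is
    suppressed at insertion time instead.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown degradation mode {mode!r}")
    if mode == "missing_tsd":
        return sequence
    if mode == "missing_tir":
        if rng.random() < 0.5:
            return sequence[template.tir_length :]
        return sequence[: -template.tir_length]
    s, e = template.cds_span
    if mode == "internal_deletion":
        cds_len = e - s
        cut = int(cds_len * float(rng.uniform(0.4, 0.6)))
        start = s + (cds_len - cut) // 2
        return sequence[:start] + sequence[start + cut :]
    # orf_disrupted: premature stop strictly before residue 500, plus one
    # every 400 codons so no downstream restart can reach 500 aa either
    n_codons = (e - s) // 3
    max_res = min(499, n_codons - 2)
    first = int(rng.integers(50, max_res))
    out = list(sequence)
    for res in [first] + list(range(first + 400, n_codons - 2, 400)):
        i = s + 3 * res
        out[i : i + 3] = "TAA"
    return "".join(out)


# ---------------------------------------------------------------------------
# Whole-genome assembly


@dataclass
class SimDataset:
    config: SimConfig
    genome: NucSequence
    templates: dict[str, TransposonTemplate]
    copies: list[PlantedCopy]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "queries": outdir / "queries.fasta",
            "bed": outdir / "truth.bed",
            "json": outdir / "truth.json",
        }
        write_fasta(paths["genome"], [self.genome])
        write_fasta(paths["queries"], [t.transposase_prot() for t in self.templates.values()])
        with open(paths["bed"], "w") as fh:
            for c in self.copies:
                fh.write(
                    f"{c.contig}\t{c.realized_span[0]}\t{c.realized_span[1]}\t"
                    f"{c.type_id}:{c.copy_index}\t{int(1000 * c.target_divergence)}\t{c.strand}\n"
                )
        payload = {
            "config": dataclasses.asdict(self.config),
            "genome_id": self.genome.id,
            "genome_length": len(self.genome),
            "templates": {
                t.type_id: dataclasses.asdict(t) for t in self.templates.values()
            },
            "copies": [dataclasses.asdict(c) for c in self.copies],
        }
        with open(paths["json"], "w") as fh:
            json.dump(payload, fh, indent=1, default=list)
        return paths


def _choose_sites(
    background: str,
    tsd: str,
    n_needed: int,
    min_spacing: int,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Non-overlapping, well-spaced TSD sites; sites are written into the
    background where too few occur naturally."""
    margin = 6000
    positions = []
    i = background.find(tsd, margin)
    while i != -1 and i < len(background) - margin:
        positions.append(i)
        i = background.find(tsd, i + 1)
    spaced: list[int] = []
    last = -(10**12)
    for p in positions:
        if p - last >= min_spacing:
            spaced.append(p)
            last = p
    if len(spaced) < n_needed:
        bg = list(background)
        usable = len(background) - 2 * margin
        step = usable // (n_needed + 1)
        if step < min_spacing:
            raise ValueError(
                f"genome of {len(background)} bp cannot host {n_needed} copies "
                f"at {min_spacing} bp spacing"
            )
        spaced = [margin + (k + 1) * step for k in range(n_needed)]
        for p in spaced:
            bg[p : p + 4] = tsd
        background = "".join(bg)
    idx = rng.permutation(len(spaced))[:n_needed]
    return background, sorted(int(spaced[j]) for j in idx)


def _copies_per_type(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    c = cfg.copies_per_type
    if isinstance(c, int):
        return [c] * cfg.n_types
    if isinstance(c, tuple):
        lo, hi = c
        return [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_types)]
    if len(c) != cfg.n_types:
        raise ValueError("copies_per_type list length must equal n_types")
    return [int(x) for x in c]


def generate_dataset(config: SimConfig) -> SimDataset:
    """Build the genome: background + planted, evolved, possibly degraded copies.

    Each copy is integrated at an existing (or guaranteed) TSD site with
    cut-and-paste semantics: the site 4-mer stays on the left flank and a
    fresh copy is appended on the right, so intact copies are flanked by
    identical 4-mers.  Divergence is applied to the whole element but not
    to the TSD flanks (they are genomic context created at integration).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    motifs = TIR_MOTIFS
    templates: dict[str, TransposonTemplate] = {}
    for t in range(config.n_types):
        tlo, thi = config.tir_length_range
        templates_id = f"PB-sim-{t + 1}"
        templates[templates_id] = build_template(
            rng,
            type_id=templates_id,
            tir_length=int(rng.integers(tlo, thi + 1)),
            tir_motif=motifs[0] if rng.random() < 0.55 else motifs[int(rng.integers(1, 4))],
            transposase_aa_range=config.transposase_aa_range,
            tsd=config.tsd,
        )

    per_type = _copies_per_type(config, rng)
    n_total = sum(per_type)
    background = _random_nuc(rng, config.genome_length, config.gc_fraction)
    background, sites = _choose_sites(
        background, config.tsd, n_total, config.min_spacing_bp, rng
    )

    # plan copies, then assign shuffled sites so families interleave
    plan: list[tuple[str, int, float, str, str]] = []  # type, idx, K, strand, integrity
    grid = config.divergence_grid
    for t_idx, (tid, n_copies) in enumerate(zip(templates, per_type)):
        family_k = grid[t_idx % len(grid)]
        for ci in range(n_copies):
            integrity = "intact"
            if rng.random() < config.truncation_fraction:
                integrity = DEGRADE_MODES[int(rng.integers(len(DEGRADE_MODES)))]
            strand = "+" if rng.random() < 0.5 else "-"
            plan.append((tid, ci, family_k, strand, integrity))
    site_order = rng.permutation(n_total)
    assignment = sorted(zip((sites[i] for i in range(n_total)), site_order), key=lambda x: x[0])

    pieces: list[str] = []
    copies: list[PlantedCopy] = []
    cursor = 0
    offset = 0
    for site, plan_idx in assignment:
        tid, ci, family_k, strand, integrity = plan[plan_idx]
        tmpl = templates[tid]
        preserve = tmpl.cds_span if integrity in ("intact", "missing_tir", "missing_tsd") else None
        seq = evolve_copy(tmpl.full_sequence, family_k, config.kappa, rng, preserve)
        seq = degrade_copy(seq, tmpl, integrity, rng) if integrity != "intact" else seq
        if strand == "-":
            seq = reverse_complement(seq)
        insert_at = site + 4  # after the left TSD 4-mer
        pieces.append(background[cursor:insert_at])
        pieces.append(seq)
        start = insert_at + offset
        end = start + len(seq)
        # ground truth is a property of the *realized* copy: an "intact"
        # insertion must still encode a >=500 aa transposase AND keep a
        # detectable terminal signature (TSD context + TIR, evaluated at
        # the known true boundaries with the pipeline's detectability rule)
        realized_intact = False
        if integrity == "intact":
            from .boundaries import tir_pair_detectable
            from .transposase import find_orfs

            _, longest = find_orfs(seq)
            orf_ok = longest is not None and longest.length_aa >= 500
            ctx = background[site : site + 4] + seq + config.tsd
            realized_intact = orf_ok and tir_pair_detectable(ctx)
        if integrity == "missing_tsd":
            # no duplication: only the pre-existing site 4-mer flanks the copy
            cursor = insert_at
        else:
            pieces.append(config.tsd)
            offset += 4
            cursor = insert_at
        offset += len(seq)
        copies.append(
            PlantedCopy(
                type_id=tid,
                copy_index=ci,
                contig=config.contig_name,
                strand=strand,
                target_divergence=family_k,
                integrity=integrity,
                realized_span=(start, end),
                is_intact=realized_intact,
                tsd=config.tsd if integrity != "missing_tsd" else "",
            )
        )
    pieces.append(background[cursor:])
    genome = NucSequence(config.contig_name, "".join(pieces))
    return SimDataset(config=config, genome=genome, templates=templates, copies=copies)
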