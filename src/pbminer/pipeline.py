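"""End-to-end pipeline: mine -> cluster -> boundaries -> copies -> domains
-> divergence -> report, with deterministic, manifest-stamped outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import divergence as dv
from . import report as rp
from .boundaries import (
    ElementModel,
    annotate_copy,
    call_element,
    cluster_candidates,
    count_copies,
)
from .mine import MiningConfig, filter_hits, merge_hits_to_loci, search_genome
from .seqcore import NucSequence, ProtSequence, read_fasta, write_fasta
from .simulate import SimConfig
from .transposase import annotate_domains, find_orfs, tir_motif_profile

log = logging.getLogger("pbminer")


@dataclass
class PipelineConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    sim: SimConfig | None = None
    seed: int = 0
    outdir: str = "pbminer_out"
    bootstrap_replicates: int = 200
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        """Range checks on every threshold; violations are returned, never fixed."""
        violations = list(self.mining.violations())
        if self.sim is not None:
            try:
                self.sim.validate()
            except ValueError as e:
                violations.append(str(e))
        if self.bootstrap_replicates < 1:
            violations.append("bootstrap_replicates must be >= 1")
        return violations


def validate_config(config: PipelineConfig) -> list[str]:
    return config.validate()


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from nested dicts; unknown keys are rejected."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "mining" in kwargs and isinstance(kwargs["mining"], dict):
        mk = {f.name for f in dataclasses.fields(MiningConfig)}
        bad = set(kwargs["mining"]) - mk
        if bad:
            raise KeyError(f"unknown mining config keys: {sorted(bad)}")
        kwargs["mining"] = MiningConfig(**kwargs["mining"])
    if "sim" in kwargs and isinstance(kwargs["sim"], dict):
        sk = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(kwargs["sim"]) - sk
        if bad:
            raise KeyError(f"unknown sim config keys: {sorted(bad)}")
        sim = dict(kwargs["sim"])
        for tup in ("divergence_grid", "copies_per_type", "tir_length_range",
                    "transposase_aa_range"):
            if tup in sim and isinstance(sim[tup], list):
                sim[tup] = tuple(sim[tup])
        kwargs["sim"] = SimConfig(**sim)
    return PipelineConfig(**kwargs)


def annotate_genome(
    genome, queries: list[ProtSequence], cfg: MiningConfig | None = None
) -> dict:
    """The full annotation chain on an in-memory genome.

    Returns a dict with hits, loci, clusters and fully populated
    ElementModels (boundaries, class, consensus, copy counts, per-copy
    intactness with TSD-refined spans).
    """
    cfg = cfg or MiningConfig()
    t0 = time.time()
    hits = search_genome(genome, queries, cfg)
    kept = filter_hits(hits, cfg)
    log.info("search: %d hits, %d after coverage/identity filter (%.1fs)",
             len(hits), len(kept), time.time() - t0)
    if not kept:
        return {"hits": hits, "filtered_hits": [], "loci": [], "clusters": [],
                "elements": []}
    loci = merge_hits_to_loci(kept, genome, cfg)
    clusters = cluster_candidates(loci, cfg)
    log.info("merged into %d loci, %d clusters", len(loci), len(clusters))
    elements: list[ElementModel] = []
    index_cache: dict = {}
    for cl in clusters:
        el = call_element(cl, cfg)
        if el.element_class in ("FL", "transposon_like") and el.consensus is not None:
            n, copy_hits = count_copies(genome, el, cfg, index_cache=index_cache)
            el.copy_count = n
            el.copy_hits = copy_hits
            intact = 0
            for h in copy_hits:
                ann = annotate_copy(h, genome, cfg, expected_tsd=el.tsd)
                h.is_intact = ann.is_intact
                h.tsd = ann.tsd
                if ann.refined_span is not None:
                    h.span = ann.refined_span
                intact += int(ann.is_intact)
            el.intact_copy_count = intact
        elements.append(el)
    log.info("annotated %d element models (%.1fs total)", len(elements), time.time() - t0)
    return {
        "hits": hits,
        "filtered_hits": kept,
        "loci": loci,
        "clusters": clusters,
        "elements": elements,
    }


# ---------------------------------------------------------------------------
# File emission


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_outputs(result: dict, genome, outdir: str | Path, cfg: MiningConfig) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = paths["hits"] = outdir / "hits.tsv"
    with open(p, "w") as fh:
        fh.write("query_id\tcontig\tstrand\tframe\tstart\tend\tscore\tidentity\t"
                 "coverage\tevalue\n")
        for h in result["filtered_hits"]:
            fh.write(
                f"{h.query_id}\t{h.contig}\t{h.strand}\t{h.frame}\t{h.nuc_span[0]}\t"
                f"{h.nuc_span[1]}\t{h.score:.1f}\t{h.identity:.4f}\t"
                f"{h.coverage_query:.4f}\t{h.evalue:.3e}\n"
            )

    p = paths["loci_bed"] = outdir / "loci.bed"
    with open(p, "w") as fh:
        for l in result["loci"]:
            fh.write(f"{l.contig}\t{l.extended_span[0]}\t{l.extended_span[1]}\t"
                     f"{l.locus_id}\t0\t.\n")
    paths["loci_fasta"] = outdir / "loci.fasta"
    write_fasta(paths["loci_fasta"], [l.sequence for l in result["loci"]])

    elements = result["elements"]
    cons = [e.consensus for e in elements if e.consensus is not None]
    paths["elements_fasta"] = outdir / "elements.fasta"
    write_fasta(paths["elements_fasta"], cons)

    p = paths["types"] = outdir / "types.tsv"
    with open(p, "w") as fh:
        fh.write("type_id\tclass\telement_length\ttir_length\ttsd\tcopy_count\t"
                 "intact_copy_count\n")
        for e in elements:
            length = e.boundaries[1] - e.boundaries[0] if e.boundaries else 0
            fh.write(f"{e.type_id}\t{e.element_class}\t{length}\t{e.tir_length}\t"
                     f"{e.tsd or '-'}\t{e.copy_count}\t{e.intact_copy_count}\n")

    p = paths["copies_bed"] = outdir / "copies.bed"
    with open(p, "w") as fh:
        for e in elements:
            for i, h in enumerate(e.copy_hits):
                fh.write(f"{h.contig}\t{h.span[0]}\t{h.span[1]}\t{e.type_id}:{i}\t"
                         f"{int(1000 * h.identity)}\t{h.strand}\n")

    p = paths["gff3"] = outdir / "elements.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in elements:
            gb = e.genomic_boundaries()
            if gb is None:
                continue
            contig, gs, ge = gb
            strand = e.reference_orientation
            fh.write(f"{contig}\tpbminer\ttransposable_element\t{gs + 1}\t"
                     f"{ge}\t.\t{strand}\t.\tID={e.type_id};class={e.element_class}"
                     f";tsd={e.tsd or '-'}\n")
            locus = e.reference_locus()
            off = locus.extended_span[0]
            L = len(locus.sequence)
            for name, span in (("five_prime_TIR", e.tir_5p_span),
                               ("three_prime_TIR", e.tir_3p_span)):
                if span:
                    s2, e2 = span
                    if strand == "-":
                        s2, e2 = L - e2, L - s2
                    fh.write(f"{contig}\tpbminer\tterminal_inverted_repeat\t"
                             f"{off + s2 + 1}\t{off + e2}\t.\t{strand}\t.\t"
                             f"Parent={e.type_id};kind={name}\n")

    # transposase domains + TIR motif logo
    p = paths["domains"] = outdir / "domains.tsv"
    with open(p, "w") as fh:
        fh.write("type_id\torf_len\td1\td2\td3\td1_d2\td2_d3\tcrd_start\tcys_positions\n")
        for e in elements:
            if e.consensus is None:
                continue
            _, longest = find_orfs(e.consensus)
            if longest is None:
                continue
            dom = annotate_domains(longest.protein.residues.rstrip("*"))
            ddd = dom.ddd or ("-", "-", "-")
            fh.write(
                f"{e.type_id}\t{longest.length_aa}\t{ddd[0]}\t{ddd[1]}\t{ddd[2]}\t"
                f"{dom.d1_d2_spacing or '-'}\t{dom.d2_d3_spacing or '-'}\t"
                f"{dom.crd[0] if dom.crd else '-'}\t"
                f"{','.join(map(str, dom.crd)) if dom.crd else '-'}\n"
            )

    tirs = []
    for e in elements:
        if e.tir_5p_span and e.boundaries and e.source_cluster:
            seq = e.source_cluster.oriented_member_seq(e.reference_index)
            t5 = seq[e.tir_5p_span[0] : e.tir_5p_span[1]]
            if len(t5) >= 5:
                tirs.append(t5)
    if tirs:
        paths["tir_logo"] = outdir / "tir_logo.tsv"
        paths["tir_logo"].write_text(tir_motif_profile(tirs).to_table())

    # divergence + landscape
    contigs = [genome] if isinstance(genome, NucSequence) else list(genome)
    glen = sum(len(c) for c in contigs)
    p = paths["divergence"] = outdir / "divergence.tsv"
    triples = []
    with open(p, "w") as fh:
        fh.write("type_id\tcopy_idx\tP\tQ\tK\tsites\n")
        for e in elements:
            if e.consensus is None:
                continue
            for i, (hit, est) in enumerate(
                dv.copy_divergences(e.copy_hits, e.consensus, genome)
            ):
                fh.write(f"{e.type_id}\t{i}\t{est.P:.5f}\t{est.Q:.5f}\t{est.K:.5f}\t"
                         f"{est.sites}\n")
                triples.append((e.type_id, hit.span[1] - hit.span[0], est))
    ls = dv.landscape(triples, glen)
    paths["landscape"] = outdir / "landscape.tsv"
    paths["landscape"].write_text(ls.to_table())

    row = rp.summarize_species(elements)
    p = paths["summary"] = outdir / "summary.tsv"
    with open(p, "w") as fh:
        fh.write("taxon\torder\tspecies\tn_fl_types\tn_intact_types\n")
        fh.write(f"{row.taxon}\t{row.order}\t{row.species}\t{row.n_fl_types}\t"
                 f"{row.n_intact_types}\n")
    return paths


def run_pipeline(
    config: PipelineConfig,
    genome_path: str | Path | None = None,
    queries_path: str | Path | None = None,
) -> dict:
    """All-in-one run: optional simulation, annotation, reports, manifest.

    With ``config.sim`` set and no genome path, the genome is simulated
    first and truth files plus a recovery report are emitted.
    """
    logging.basicConfig(level=config.log_level)
    violations = config.validate()
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    truth = None
    if genome_path is None:
        if config.sim is None:
            raise ValueError("either a genome path or a sim config is required")
        from .simulate import generate_dataset

        t0 = time.time()
        ds = generate_dataset(config.sim)
        sim_paths = ds.write(outdir / "sim")
        stages.append({"stage": "simulate", "seconds": round(time.time() - t0, 2),
                       "outputs": {k: str(v) for k, v in sim_paths.items()}})
        genome = ds.genome
        queries = [t.transposase_prot() for t in ds.templates.values()]
        truth = ds
    else:
        genome = read_fasta(genome_path)
        queries = read_fasta(queries_path, protein=True)

    t0 = time.time()
    result = annotate_genome(genome, queries, config.mining)
    paths = write_outputs(result, genome, outdir, config.mining)
    stages.append({"stage": "annotate", "seconds": round(time.time() - t0, 2),
                   "outputs": {k: str(v) for k, v in paths.items()}})

    if truth is not None:
        rep = rp.evaluate_recovery(result["elements"], truth.copies)
        p = outdir / "recovery.json"
        payload = rep.summary()
        payload["per_type"] = {
            k: dataclasses.asdict(v) for k, v in rep.per_type.items()
        }
        p.write_text(json.dumps(payload, indent=1))
        result["recovery"] = rep

    manifest = {
        "seed": config.seed,
        "mining": dataclasses.asdict(config.mining),
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "stages": stages,
        "output_hashes": {
            k: _hash_file(Path(v)) for k, v in
            sorted((k, v) for s in stages for k, v in s["outputs"].items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
    result["manifest"] = manifest
    return result
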