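# Methods

## Scope and model

pbminer re-implements a de-novo annotation protocol for piggyBac (PB)
DNA transposons and validates it by parameter recovery on simulated
genomes.  A piggyBac element is modeled as

```
... host | TSD | 5'TIR ---- transposase ORF ---- 3'TIR | TSD | host ...
```

with a 4 bp target-site duplication (TSD, canonically `TTAA`) created at
integration on both flanks, terminal inverted repeats (TIRs) of 4–600 bp
whose 5' ends carry one of the conserved motifs `CACTA/CCCTC/CCCTT/CCCAT`,
and a single ORF encoding a transposase of ≥ 500 aa with a catalytic DDD
triad (D1–D2 spacing ≈ 78–85 aa, D2–D3 ≈ 98–113 aa) and a C-terminal
cysteine-rich domain (CRD) of eight regularly spaced cysteines.

Classification follows the protocol's definitions:

* **FL (full length)** — both TIRs and both TSD flanks detectable;
* **transposon-like** — only one TIR or one TSD detectable;
* **intact copy** — an FL copy that additionally encodes a ≥ 500 aa
  transposase (inclusive bound); a proxy for transposition competence.

## Pipeline stages

1. **Translated search** (`mine.search_genome`).  Protein queries vs all
   six reading frames: exact protein 4-mer seeds, grouped into diagonal
   bands with a two-seed trigger, Smith–Waterman extension (BLOSUM62,
   gap open 11 / extend 1), Karlin–Altschul E-values with
   `K = 0.041, λ = 0.267` and `n = 2 ×` genome length (both strands).
   Hits with `E > 1e-4` are dropped; survivors are filtered at query
   coverage > 30% and identity > 80% (strict inequalities).  The two-seed
   trigger is a heuristic: with 4-mer seeds a single-hit trigger floods
   extension with chance matches; planted elements always carry many
   co-diagonal seeds.
2. **Locus building** (`merge_hits_to_loci`).  Hits within 3 kb on a
   contig merge (strand-blind) into a core span, extended by 4 kb flanks.
3. **Clustering** (`boundaries.cluster_candidates`).  Greedy centroid
   clustering, longest locus first, joining at ≥ 50% global identity.
   Identity is computed on the merged-hit *core* regions in both
   orientations: the 4 kb flanks are unrelated genomic context and would
   dilute any identity threshold into meaninglessness.
4. **Boundary detection** (`call_element`).  The primary route is
   TSD-anchored: the member-agreement extent (exact 12-mer matches between
   cluster members, dominant diagonal band) localizes the element on a
   reference copy — members share only the element, not their flanks —
   and `TTAA ... TTAA` pairs near the extent edges are confirmed by a
   *terminal-signature* alignment: the region starting at the hypothesized
   5' boundary (including the 4 bp TSD context) aligned against the
   reverse complement of the 3' region.  Because `TTAA` is palindromic the
   TSD and TIR form one contiguous inverted repeat; scoring them jointly
   makes short eroded TIRs detectable exactly when their boundary
   signature is.  The signature must be flush (within 6 bp) and score
   ≥ 8 (≈ 8 bp of clean match) — below that, chance inverted matches at
   arbitrary boundary pairs are frequent.  Among candidate TTAA pairs the
   flushest wins, ties broken toward the strongest signature: a TIR that
   itself contains `TTAA` creates flush nested pseudo-boundaries, and the
   outer (full-TIR) pair is the one with the higher score.  If the reference copy cannot anchor boundaries (e.g.
   its TIR was deleted), the next-longest members are tried.  A fallback
   inverted-repeat-first search (iterative masking for top-N pairs)
   handles clusters without TTAA anchors; non-canonical TSDs (`TATG`-like)
   are accepted only flush with a strong (score ≥ 12) TIR pair, since a
   chance matching 4-mer pair near weak repeats is common.
5. **Consensus and copy counting** (`count_copies`).  The member copies
   are trimmed to the element, aligned center-star around the reference
   element, and majority-called into a consensus.  The consensus is then
   scanned against the genome (both strands) with exact 12-mer seeds,
   diagonal banding (≥ 3 seeds) and local alignment; co-linear HSPs are
   chained (a copy with an internal deletion aligns as two segments that
   the affine gap model will not bridge) and hits overlapping > 50%
   reciprocally collapse to the best score.  Copies are retained at
   coverage > 40% and identity > 80%.
6. **Per-copy intactness** (`annotate_copy`).  Each retained copy is
   re-annotated on its own flanks with the same TSD-anchored rule; a copy
   is intact iff one consistent boundary pair carries the terminal
   signature *and* a TSD matching its family's TSD *and* the copy's
   longest ORF is ≥ 500 aa.  TSD-anchored boundaries replace raw
   alignment spans, which is what makes copy boundaries exact to the
   base even for diverged copies (local alignment trims mismatching
   terminal bases; the duplicated `TTAA` does not mutate in the
   simulation, matching its origin as genomic context).
7. **Transposase characterization** (`transposase`).  Rule-based ORF
   scan (ATG starts, standard code, all six frames, ≥ 100 aa reported),
   DDD triad as the aspartate triple with spacings closest (L1) to the
   observed envelopes within search ranges widened by ~8 aa, CRD as the
   max-cysteine 120 aa window over the C-terminal third, and NTD / DDBD1 /
   DDBD2 spans positioned relative to the triad (coarse by design and
   flagged as heuristic).  Profile-HMM and gene-prediction tools are
   deliberately replaced by these rule-based locators: downstream use is
   lengths and residue positions only.
8. **Phylogeny** (`phylo`).  Center-star protein MSA, p-distances with
   Poisson correction (`d = −ln(1 − p)`, p ≥ 0.95 capped at 5.0 and
   flagged), Saitou–Nei neighbor joining with deterministic tie-breaking
   (row-major smallest index pair; negative branch lengths clamped to
   zero, deficit moved to the sister), nonparametric bootstrap over
   columns.  A query is assigned to a clade only when the smallest
   bootstrap-supported (> 80) group containing it holds references of
   exactly one clade and no outgroup.  Distance NJ + standard bootstrap
   substitutes for maximum-likelihood inference with ultrafast bootstrap;
   for clade-level assignment of well-separated families the two agree,
   and the substitution keeps the package self-contained and exactly
   reproducible.
9. **Divergence** (`divergence`).  Kimura 2-parameter distance per copy
   vs its consensus, `K = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` over gap- and
   N-free columns; landscapes accumulate copy bp into right-open 1%
   bins of `100·K`, normalized by genome length (per-family decomposition
   retained).  Saturated pairs are excluded from bins and tallied
   separately.  No CpG adjustment is applied.

## The simulator and what it does (not) emulate

`simulate.generate_dataset` builds an i.i.d. background genome at a
configured GC (default 0.40, 2 Mb), designs transposon families
(`build_template`) and integrates copies at existing (or, when scarce,
written-in) `TTAA` sites with cut-and-paste semantics: the site 4-mer
stays on the left and a fresh copy is appended on the right, so intact
copies are flanked by identical 4-mers.  Divergence is applied to the
whole element but never to the TSD flanks (they are created at
integration time).  Per-copy substitutions follow the exact K2P
transition probabilities at the target distance (transition/transversion
rate ratio κ = 2), so the expected K2P estimate equals the target.

Defaults define the study conditions used throughout the tests: 12
families, 4–8 copies each, family divergences cycling through
K ∈ {0, 0.02, 0.05, 0.10}, 20% of copies degraded (one of: a TIR
deleted, the TSD duplication suppressed, ≥ 30% of the CDS deleted, or
premature stops written into the ORF), strands Bernoulli(½), insertions
≥ 12 kb apart.  The spacing keeps each element's 4 kb candidate flanks
free of neighboring elements so boundary-recovery scoring is
unambiguous; nested insertions are out of scope.

Template design choices that make ground truth exact: transposase
residues outside the designed DDD/CRD positions are drawn from a pool
without D and C, so the domain locators can be scored against unique
planted positions; codons are resampled until the designed CDS is the
only ORF ≥ 450 aa outside its own frame, and the 5' spacer ends with an
in-frame stop, so the ORF-disruption degradation (premature stops every
400 codons) reliably abolishes any ≥ 500 aa product.  Copies planted as
intact evolve under a purifying-selection emulation (substitutions
creating premature stops, or hitting the start codon, are reverted);
without it, essentially every copy at K ≥ 0.02 would acquire a nonsense
substitution and the intact label would be vacuous.  The K bias from
reverting ~4% of CDS substitutions is well inside the 0.015 calibration
band.

Ground-truth intactness is a property of the *realized* copy: an
insertion planted as intact is labeled intact only if its realized
longest ORF is ≥ 500 aa and its terminal signature is detectable at the
known true boundaries under the same alignment rule the pipeline uses
(`tir_pair_detectable`).  Detectability at a fixed identity threshold is
inherently operational — the original protocol resolved it by manual
inspection — and defining truth by the same operational rule, evaluated
at truth positions, means recovery tests measure localization and
classification rather than re-litigating the detectability boundary.

What the simulator does **not** emulate, and hence what passing tests do
not show about real genomes: no indel evolution (substitutions plus
discrete truncations only), no nested or fragmented insertions, no host
repeat families or low-complexity sequence competing with seeds, no
MITEs or domesticated transposase genes, i.i.d. background rather than
real isochore/repeat structure, and query proteins that are the true
family ancestors rather than a curated cross-species panel.  Recovery
numbers on this fixture are therefore upper bounds on real-genome
performance of the identical code path.

## Numerical and interface conventions

* Coordinates are 0-based half-open everywhere; 1-based inclusive only
  in exported GFF3.
* Alignment identity = identical columns / all alignment columns (gap
  columns included); coverage = aligned query span / query length.
  Protein scoring BLOSUM62 with gap 11/1; nucleotide +1/−2 with gap 5/2;
  `N` scores as a mismatch, `X` scores 0 (BLOSUM62 row).
* "Over X%" thresholds from the protocol are strict inequalities.
* Alignment backend is Biopython's `PairwiseAligner` (C implementation);
  its deterministic co-optimal ordering supplies tie-breaking.  Brute
  force enumeration oracles in the test suite verify scores on all short
  inputs.
* Percentages print with one decimal, rounded half away from zero,
  matching the survey table.
* Determinism: every stochastic step takes a `numpy` Generator seeded
  from the configuration; two runs with the same configuration produce
  byte-identical FASTA/TSV/BED/GFF3/Newick outputs (the run manifest
  embeds wall-clock timings and is exempt).

## Problem sizes used by the shipped analyses and tests

The standard validation genome is 2 Mb with 12 families (~90 copies);
the full pipeline annotates it in a few minutes on one core.  Unit and
property tests use 120–400 kb genomes, alignment oracles cover all
sequence pairs up to length 6 by exhaustive enumeration (seeded random
sample of several dozen pairs), K2P calibration uses 30–40 replicate
copies of a ~3 kb element per grid point, and bootstrap demonstrations
use 100–200 replicates (the operation supports any count).

## Known limitations

* TIRs shorter than ~8 bp sit below the chance floor of de-novo
  inverted-repeat detection; such families are only recovered through
  their TTAA anchoring, and their reported TIR lengths are unreliable.
* Non-canonical TSDs are only called flush with strong TIR pairs; a
  family with both a non-canonical TSD and a short TIR will be classed
  transposon-like.
* The center-star MSA is O(n²) in members and approximate far from the
  center; fine for consensus building at ≤ 20% divergence, not a
  substitute for progressive alignment at deep divergence.
* Clade assignment inherits NJ's sensitivity to long-branch attraction;
  the > 80 support guard makes it abstain rather than err.
* `evaluate_recovery` matches calls to truth by ≥ 50% reciprocal overlap;
  heavily fragmented calls could double-count in pathological cases not
  seen under the default conditions.
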