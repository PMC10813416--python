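# pbminer

De-novo mining, annotation and evolutionary-dynamics analysis of
**piggyBac (PB) DNA transposons**, validated end to end on simulated
genomes with planted elements of known ground truth.

piggyBac elements are cut-and-paste DNA transposons recognizable by three
structural signatures: a 4 bp target-site duplication (TSD, canonically
`TTAA`) on both flanks, short terminal inverted repeats (TIRs, typically
4–24 bp, 5' ends dominated by `CCCTT`-like motifs), and a single ORF
encoding a transposase of ≥ 500 aa carrying a catalytic DDD aspartate
triad (D1–D2 ≈ 78–85 aa, D2–D3 ≈ 98–113 aa) and a C-terminal
cysteine-rich domain of eight cysteines.  Annotating them de novo in an
assembly means: translated homology search with transposase queries
(E < 10⁻⁴, then coverage > 30% and identity > 80%), extraction of hit
loci with 4 kb flanks, clustering at 50% identity, TIR/TSD boundary
detection, classification (full-length **FL** = both TIRs + both TSDs;
**transposon-like** = only one of either), per-family copy counting
(BLASTN-like, coverage > 40%, identity > 80%), intact-copy calling
(FL + ≥ 500 aa transposase), neighbor-joining clade assignment with
bootstrap support > 80, and Kimura 2-parameter divergence landscapes

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are transition and transversion proportions of a copy
against its family consensus: low K marks recent, potentially active
invasions.

The package is aimed at researchers studying transposable-element
content and dynamics in (compact) animal genomes, and at anyone who
needs a fully deterministic, dependency-light reference implementation
of this annotation protocol whose every stage can be scored against
planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated genome (outputs land under `results/`, which is generated, not
shipped):

```bash
python analysis/01_simulate_genome.py      # plant 12 families in 2 Mb
python analysis/02_mine_and_annotate.py    # mine -> cluster -> boundaries -> copies
python analysis/03_transposase_domains.py  # ORF / DDD / CRD tables
python analysis/04_phylogeny_clades.py     # NJ + bootstrap clade assignment
python analysis/05_divergence_landscape.py # K2P landscape per family
python analysis/06_survey_table_summary.py # published survey arithmetic
```

`01` prints

```
genome: 2,193,315 bp, 12 families, 90 planted copies (74 intact)
```

and `02` recovers every family with exact boundaries and copy counts:

```
82 filtered hits -> 81 loci -> 12 types (12 FL) in 272s
  PB-type-1: FL, tir 16 bp, tsd TTAA, 8 copies (7 intact)
  PB-type-2: FL, tir 13 bp, tsd TTAA, 7 copies (5 intact)
  ...
recovery: recall 1.00, precision 1.0, intact-label accuracy 1.0
```

`03` shows each recovered transposase with its catalytic-triad spacings
inside the family-typical envelopes, e.g.

```
type           orf_aa    D1    D2    D3  D1-D2  D2-D3  CRD cysteines
PB-type-1         659   236   319   420     83    101  544,556,568,...
PB-type-6         606   211   289   395     78    106  491,503,515,...
```

and `05` places each family's copies on the divergence axis where they
were planted (families simulated at K = 0 peak in the 0% bin, K = 0.10
families in the 9–10% bins; 8.8% of the genome is transposon-derived).
`06` reproduces the published survey's headline arithmetic: 212
full-length types across 37 species, 85 types with intact copies and 127
without, 7 single-type species, and phylum fractions 35.1%
(Arthropoda), 21.6% (Mollusca), 16.2% + 16.2% (Chordata, Annelida),
5.4% + 5.4% (Echinodermata, Platyhelminthes).

A `pbminer` console script exposes the same stages
(`simulate`, `mine`, `annotate`, `domains`, `tree`, `landscape`,
`report`, `run`) for use on your own FASTA inputs; see `pbminer --help`.

## Layout

```
src/pbminer/        library: seqcore, simulate, mine, boundaries,
                    transposase, phylo, divergence, report, pipeline, cli
src/pbminer/data/   transcribed species-survey table (TSV)
analysis/           numbered study drivers (write to results/)
scripts/            acceptance.py
tests/              pytest suite with brute-force oracles
docs/methods.md     model, assumptions, numerical choices, limitations
```
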