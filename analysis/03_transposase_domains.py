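#!/usr/bin/env python
"""Characterize the recovered transposases: ORFs, DDD triad, CRD, TIR motifs.

Reads the element consensus sequences produced by 02, locates the longest
ORF of each, the catalytic aspartate triad (D1-D2 within ~78-85 aa, D2-D3
within ~98-113 aa) and the C-terminal cysteine-rich domain, and prints the
family-by-family table (the same information 02 wrote to domains.tsv and
tir_logo.tsv).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pbminer.seqcore import read_fasta
from pbminer.transposase import annotate_domains, find_orfs

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    elements = read_fasta(ROOT / "annotation" / "elements.fasta")
    print(f"{'type':<14}{'orf_aa':>7}{'D1':>6}{'D2':>6}{'D3':>6}"
          f"{'D1-D2':>7}{'D2-D3':>7}  CRD cysteines")
    for el in elements:
        _, longest = find_orfs(el)
        if longest is None:
            print(f"{el.id:<14}      -")
            continue
        dom = annotate_domains(longest.protein.residues.rstrip("*"))
        ddd = dom.ddd or ("-", "-", "-")
        crd = ",".join(map(str, dom.crd)) if dom.crd else "-"
        print(f"{el.id:<14}{longest.length_aa:>7}{ddd[0]:>6}{ddd[1]:>6}{ddd[2]:>6}"
              f"{dom.d1_d2_spacing or '-':>7}{dom.d2_d3_spacing or '-':>7}  {crd}")


if __name__ == "__main__":
    main()
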