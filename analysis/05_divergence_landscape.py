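#!/usr/bin/env python
"""Summarize the divergence landscape of the annotated genome.

Reads the per-copy Kimura divergences written by 02 and reports, per
family, where its copies sit on the K axis — families planted at K = 0
appear in the lowest bins (recent, potentially active invasions), the
K = 0.10 families ten bins up (older invasions).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    div = pd.read_csv(ROOT / "annotation" / "divergence.tsv", sep="\t")
    ls = pd.read_csv(ROOT / "annotation" / "landscape.tsv", sep="\t")
    print(f"{len(div)} copies across {div.type_id.nunique()} families")
    per_type = div.groupby("type_id")["K"].agg(["count", "mean"])
    for tid, row in per_type.iterrows():
        bins = ls[ls.type_id == tid]
        peak = int(bins.loc[bins.coverage_pct.idxmax(), "bin_pct"]) if len(bins) else 0
        print(f"  {tid}: {int(row['count'])} copies, mean K {row['mean']:.3f}, "
              f"peak bin {peak}%")
    total = ls.coverage_pct.sum()
    print(f"total transposon coverage {total:.3f}% of the genome")


if __name__ == "__main__":
    main()
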