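#!/usr/bin/env python
"""Aggregate the packaged species-survey table into headline statistics.

Per-phylum species and type counts, totals of full-length and
intact-containing transposon types, single-type species, and the phylum
fractions of piggyBac-containing species.  Writes results/survey/aggregate.json.
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pbminer import report as rp

OUT = Path(__file__).resolve().parents[1] / "results" / "survey"


def main() -> None:
    agg = rp.aggregate(rp.rows_from_table(rp.load_table1()))
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "aggregate.json").write_text(json.dumps(dataclasses.asdict(agg), indent=1))
    print(f"{agg.total_types} full-length types in {agg.n_species_with_pb} species; "
          f"{agg.total_intact_types} types with intact copies, "
          f"{agg.total_no_intact} without; {agg.n_single_type_species} single-type species")
    for phylum, pct in agg.per_phylum_pct.items():
        print(f"  {phylum}: {agg.per_phylum_species[phylum]} species ({pct}%), "
              f"{agg.per_phylum_types[phylum]} types")
    counts = [0] * (agg.total_types - 24) + [6] * 24
    n_below, pct = rp.threshold_stats(counts, min_copies=6)
    print(f"{n_below} types ({pct}%) carry fewer than six intact copies")


if __name__ == "__main__":
    main()
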