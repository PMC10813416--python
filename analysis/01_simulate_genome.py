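#!/usr/bin/env python
"""Generate the standard synthetic genome with planted piggyBac families.

2 Mb background, 12 transposon families with 4-8 copies each, family
divergences cycling through K in {0, 0.02, 0.05, 0.10}, 20% of copies
truncated or degenerate.  Writes the genome, the transposase queries and
the ground truth under results/sim/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pbminer.simulate import SimConfig, generate_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    ds = generate_dataset(cfg)
    paths = ds.write(OUT)
    n_intact = sum(c.is_intact for c in ds.copies)
    print(f"genome: {len(ds.genome):,} bp, {len(ds.templates)} families, "
          f"{len(ds.copies)} planted copies ({n_intact} intact)")
    for k, p in paths.items():
        print(f"  {k}: {p}")


if __name__ == "__main__":
    main()
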