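#!/usr/bin/env python
"""Simulate the haploid Gd x Vx cross at the study's conditions.

One 20 Mb chromosome carrying a 100 cM map with 2,000 evenly spaced
markers; 192 haploid progeny; phenotype follows the Gd allele at the
causal locus (10 Mb) with full penetrance; a 48-member downward-growing
bulk is pool-sequenced at a mean of 50 reads per marker with 1% error.

Writes markers.tsv, genotypes.tsv and bulk_depths.tsv under
results/analysis/ for the downstream steps.
"""

from pathlib import Path

import numpy as np

from mossmap.cross import (genotype_table, make_bulk, simulate_cross,
                           simulate_pool_depths, write_depth_table,
                           write_genotype_table)
from mossmap.genome import write_marker_map
from mossmap.scenario import bsa_scenario

SEED = 1
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = bsa_scenario(seed=SEED)
    segregants = simulate_cross(cfg)
    n_down = sum(s.phenotype == "down" for s in segregants)
    n_up = sum(s.phenotype == "up" for s in segregants)
    print(f"simulated {len(segregants)} haploid segregants: "
          f"{n_down} down / {n_up} up (1:1 expected)")

    bulk = make_bulk(segregants, "down", cfg.n_bulk)
    rng = np.random.default_rng(SEED + 1)
    depths = simulate_pool_depths(bulk, cfg.markers, cfg.coverage,
                                  cfg.error_rate, rng)
    mean_depth = float((depths.gd_depth + depths.vx_depth).mean())
    print(f"pooled {len(bulk)} downward segregants; "
          f"mean depth {mean_depth:.1f}x over {len(depths)} markers")

    write_marker_map(cfg.markers, OUT / "markers.tsv")
    write_genotype_table(genotype_table(segregants, cfg.markers),
                         OUT / "genotypes.tsv")
    write_depth_table(depths, OUT / "bulk_depths.tsv")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
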