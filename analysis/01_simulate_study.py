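#!/usr/bin/env python
"""Generate the synthetic pea intercropping study and write it to disk.

Produces the default scenario: 6 RIL populations x 23 lines + 6 parents
(144 inbred lines), ~1000 GBS-like SNPs on 7 chromosomes, and plot-level
split-plot phenotypes for two cropping years x {pure stand, mixed stand}
x 3 blocks.  Outputs under results/data/: trial.tsv, genotypes.012.tsv,
marker_map.tsv, architecture.json.
"""

import argparse
from pathlib import Path

from peamix import simulate as sim

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results/data"))
args = ap.parse_args()

scen = sim.generate_scenario(sim.SimulationConfig(seed=args.seed))
scen.write(args.out)

t = scen.trial
print(f"wrote scenario to {args.out}/")
print(f"  lines: {scen.line_table.shape[0]} ({int(scen.line_table['is_parent'].sum())} parents)")
print(f"  plots: {len(t)} over years {sorted(t['year'].unique())}")
print(f"  markers: {scen.genotypes.n_markers}, "
      f"mean missing rate {scen.genotypes.marker_missing_rate().mean():.3f}")
print(f"  realized MS/PS genetic correlation of pea yield: "
      f"{scen.architecture.realized_corr_ms_ps:.3f}")
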