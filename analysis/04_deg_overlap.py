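#!/usr/bin/env python
"""Threshold the knockdown DEG table and test cluster-wise enrichment.

Applies the |log2FC| >= log2(1.5), padj <= 0.05 rule, then tests each
signal cluster's assigned genes for enrichment in the increased and
decreased sets (one-sided hypergeometric, BH across the family).
"""

import json
import logging

import pandas as pd

from chromkd.pipeline import RunConfig, run

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

cfg = RunConfig(seed=1, outdir="results/run", stages=("degsets",))
run(cfg)

sets = json.loads((cfg.outdir / "degsets" / "deg_sets.json").read_text())
print(f"\nDEGs: {sets['n_increased']} increased, {sets['n_decreased']} decreased "
      f"of {sets['n_universe']} tested genes")
enr = pd.read_csv(cfg.outdir / "degsets" / "cluster_enrichment.tsv", sep="\t")
if not enr.empty:
    cols = ["cluster", "direction", "n_cluster", "n_overlap", "odds_ratio",
            "p_value", "padj", "median_log2fc"]
    print(enr[cols].to_string(index=False))
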