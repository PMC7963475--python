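#!/usr/bin/env python
"""Detect niche domains on the reference world and bootstrap their support.

Builds the bipartite species-bin network, minimizes the map-equation
code length over 50 restarts, and estimates domain robustness from 20
bootstrap networks (within-cell climate resampling, Jaccard > 0.5
matching).  Prints the per-domain summary; artifacts extend
results/reference/.
"""

import json
import logging
from pathlib import Path

import pandas as pd

from nichedomains import RunConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

OUT = Path(__file__).resolve().parents[1] / "results" / "reference"


def main() -> None:
    cfg = RunConfig.from_yaml(OUT / "run_config.yaml")
    run_pipeline(cfg, stages=["network", "domains", "bootstrap"])
    part = json.load(open(OUT / "partition.json"))
    support = pd.read_csv(OUT / "support.csv")
    print(f"code length: {part['code_length']:.4f} bits over {len(part['paths'])} nodes")
    print(f"finest domains: {support.shape[0]}")
    print(support.to_string(index=False))


if __name__ == "__main__":
    main()
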