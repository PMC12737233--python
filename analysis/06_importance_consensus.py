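#!/usr/bin/env python
"""Aggregate per-model feature importances into a Borda consensus.

Each model's mean absolute attributions become tie-averaged ranks; Borda
points n - r + 1 are weighted by model accuracy and summed.  Scores above
60 mark strong cross-model agreement on a feature's importance.
"""

from pathlib import Path

import pandas as pd

from gaitpheno.config import RunConfig
from gaitpheno.pipeline import stage_consensus

cfg = RunConfig.from_yaml(Path(__file__).with_name("config.yaml"))
table = stage_consensus(cfg, Path(cfg.output_dir))

print("top-3 consensus features per phenotype:")
top = table.groupby("phenotype").head(3)
print(
    top[["phenotype", "feature", "borda_score", "strong_consensus"]]
    .round(2)
    .to_string(index=False)
)
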