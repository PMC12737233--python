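#!/usr/bin/env python
"""Phenotype-specific TUG screening cutoffs.

Per phenotype: the Youden-optimal TUG cutoff under the >= rule, compared
with the conventional uniform 13.50 s standard (precision, recall, F1,
accuracy).  Cutoffs are exploratory reference values, not definitive
clinical thresholds.
"""

from pathlib import Path

import pandas as pd

from gaitpheno.config import RunConfig
from gaitpheno.pipeline import stage_screen

cfg = RunConfig.from_yaml(Path(__file__).with_name("config.yaml"))
table = stage_screen(cfg, Path(cfg.output_dir))

print("fixed 13.50 s vs Youden-customized cutoff per phenotype:")
print(table.round(2).to_string(index=False))
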