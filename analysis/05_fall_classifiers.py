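#!/usr/bin/env python
"""Fit the per-phenotype faller models.

For each phenotype: random forest, XGBoost, decision tree, and MLP, each
tuned by grid search under stratified 5-fold CV with class weighting and
F1 scoring, refit on all subjects, and explained by mean absolute
positive-class attributions (inputs to the consensus step).
"""

from pathlib import Path

import pandas as pd

from gaitpheno.config import RunConfig
from gaitpheno.pipeline import stage_classify

cfg = RunConfig.from_yaml(Path(__file__).with_name("config.yaml"))
table = stage_classify(cfg, Path(cfg.output_dir))

print("cross-validated performance (mean over folds):")
print(
    table[["phenotype", "family", "accuracy", "precision", "recall", "f1"]]
    .round(2)
    .to_string(index=False)
)
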