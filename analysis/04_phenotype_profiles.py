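#!/usr/bin/env python
"""Summarize the phenotypes and contrast fallers vs non-fallers.

Per cluster: size, fall prevalence, mean +/- SD of every gait/clinical
variable overall and by fall history, with two-group Kruskal-Wallis
contrast p-values (alpha 0.05, uncorrected).
"""

from pathlib import Path

import pandas as pd

from gaitpheno.config import RunConfig
from gaitpheno.pipeline import stage_profile

cfg = RunConfig.from_yaml(Path(__file__).with_name("config.yaml"))
table = stage_profile(cfg, Path(cfg.output_dir))

heads = table.drop_duplicates("cluster")[["cluster", "n", "fall_prevalence_pct"]]
print("phenotype sizes and fall prevalence:")
print(heads.to_string(index=False))
key = table[table.variable.isin(["step_speed", "tug_s", "short_fes_i"])]
print("\nkey contrasts (faller vs non-faller, * = p<0.05):")
for _, r in key.iterrows():
    star = "*" if r.significant else " "
    print(f"  cluster {r.cluster} {r.variable:12s} NF {r.non_faller:>14s}  F {r.faller:>14s} {star}")
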