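#!/usr/bin/env python
"""Simulate the synthetic study cohort.

Generates 146 older-adult subjects split across four gait-phenotype
archetypes (high-cadence, cautious, intermediate, robust), each with
stride waveforms, derived gait parameters, clinical scores, and a
planted phenotype-specific fall mechanism, then writes the cohort in the
GSTRIDE-like CSV layout.
"""

from pathlib import Path

import pandas as pd

from gaitpheno.config import RunConfig
from gaitpheno.pipeline import stage_simulate

cfg = RunConfig.from_yaml(Path(__file__).with_name("config.yaml"))
workdir = Path(cfg.output_dir)
workdir.mkdir(parents=True, exist_ok=True)

cohort_dir = stage_simulate(cfg, workdir)

feats = pd.read_csv(cohort_dir / "subjects.csv", index_col="subject_id")
truth = pd.read_csv(cohort_dir / "truth.csv", index_col="subject_id")["phenotype"]
df = feats.join(truth)
print(f"simulated {len(df)} subjects -> {cohort_dir}")
print("\nper-phenotype profile (mean) and fall prevalence:")
summary = df.groupby("phenotype").agg(
    n=("fell", "size"),
    fall_prev=("fell", "mean"),
    cadence=("cadence", "mean"),
    step_speed=("step_speed", "mean"),
    tug_s=("tug_s", "mean"),
    sppb=("sppb", "mean"),
)
print(summary.round(2).to_string())
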