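"""Per-phenotype TUG screening: Youden-optimal cutoff vs the 13.50 s standard.

The decision rule is "predict faller iff TUG >= cutoff" (slower-or-equal
flagged).  Candidate cutoffs are the midpoints between consecutive distinct
sorted TUG values plus below-min and above-max sentinels; the cutoff
maximizing the Youden index J = sensitivity + specificity - 1 is chosen,
ties broken toward higher sensitivity (screening favors not missing
fallers).  Reported cutoffs are exploratory reference values, not
definitive clinical thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import confusion_metrics


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    chosen_cutoff: float
    chosen_j: float


@dataclass
class ScreeningComparison:
    fixed_cutoff: float
    custom_cutoff: float
    fixed_metrics: dict
    custom_metrics: dict


def _confusion_at(tug: np.ndarray, fell: np.ndarray, cutoff: float) -> tuple:
    pred = tug >= cutoff
    tp = int(np.sum(pred & (fell == 1)))
    fp = int(np.sum(pred & (fell == 0)))
    fn = int(np.sum(~pred & (fell == 1)))
    tn = int(np.sum(~pred & (fell == 0)))
    return tp, fp, fn, tn


def youden_threshold(tug: np.ndarray, fell: np.ndarray) -> ROCResult:
    """Youden-optimal TUG cutoff under the >= decision rule."""
    tug = np.asarray(tug, dtype=float)
    fell = np.asarray(fell, dtype=int)
    if np.any(tug <= 0):
        raise ValueError("TUG times must be positive")
    if len(np.unique(fell)) < 2:
        raise ValueError("both fallers and non-fallers required")
    v = np.unique(tug)
    candidates = np.concatenate([[v[0] - 1.0], (v[:-1] + v[1:]) / 2.0, [v[-1] + 1.0]])
    sens = np.empty(len(candidates))
    spec = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        tp, fp, fn, tn = _confusion_at(tug, fell, c)
        sens[i] = tp / (tp + fn)
        spec[i] = tn / (tn + fp)
    J = sens + spec - 1.0
    # candidates ascend, sensitivity is non-increasing: first argmax has the
    # highest sensitivity among maximal J
    best = int(np.argmax(J))
    return ROCResult(candidates, sens, spec, J, float(candidates[best]), float(J[best]))


def screening_report(
    tug: np.ndarray,
    fell: np.ndarray,
    custom_cutoff: float,
    fixed_cutoff: float = 13.50,
) -> ScreeningComparison:
    """Confusion-matrix metrics at the fixed and the customized cutoff."""
    if custom_cutoff <= 0 or fixed_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    tug = np.asarray(tug, dtype=float)
    fell = np.asarray(fell, dtype=int)
    out = []
    for c in (fixed_cutoff, custom_cutoff):
        tp, fp, fn, tn = _confusion_at(tug, fell, c)
        m = confusion_metrics(np.array([[tn, fp], [fn, tp]]))
        out.append(
            {k: m[k] for k in ("accuracy", "precision", "recall", "specificity", "f1")}
        )
    return ScreeningComparison(fixed_cutoff, round(custom_cutoff, 2), out[0], out[1])


def screening_table(
    comparisons: dict[str, ScreeningComparison]
) -> pd.DataFrame:
    """Report per phenotype: threshold and metrics, fixed vs customized.

    Values are exploratory reference values, not definitive clinical cutoffs.
    """
    rows = []
    for pheno, comp in comparisons.items():
        for which, cutoff, m in (
            ("fixed", comp.fixed_cutoff, comp.fixed_metrics),
            ("customized", comp.custom_cutoff, comp.custom_metrics),
        ):
            rows.append(
                {
                    "phenotype": pheno, "rule": which,
                    "threshold_s": f"{cutoff:.2f}",
                    "precision": m["precision"], "recall": m["recall"],
                    "f1": m["f1"], "accuracy": m["accuracy"],
                }
            )
    return pd.DataFrame(rows)
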