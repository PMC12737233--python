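"""Per-cluster phenotype profiles and within-cluster faller contrasts.

Each cluster is summarized by its size, fall prevalence (integer percent),
and mean +/- SD of every variable, overall and split by fall history.  The
faller vs non-faller contrast per variable uses the two-group
Kruskal-Wallis test (rank-based, so invariant to monotone transforms) at
alpha = 0.05 without multiple-testing correction; an optional
Benjamini-Hochberg switch is provided for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClusterProfile:
    cluster: int
    n: int
    fall_prevalence_pct: int
    summaries: pd.DataFrame  # rows: variable; cols: all/faller/nonfaller mean & sd
    p_values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def faller_contrast(values: np.ndarray, fall_labels: np.ndarray) -> tuple[float, float]:
    """Two-group Kruskal-Wallis p-value and direction of the contrast.

    Returns (p_value, direction) where direction is sign(median_faller -
    median_nonfaller).  Both groups must be non-empty; otherwise the
    contrast is undefined and (nan, nan) is returned.
    """
    values = np.asarray(values, dtype=float)
    fall_labels = np.asarray(fall_labels, dtype=int)
    mask = np.isfinite(values)
    values, fall_labels = values[mask], fall_labels[mask]
    g0 = values[fall_labels == 0]
    g1 = values[fall_labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        return float("nan"), float("nan")
    if np.ptp(values) == 0:
        return 1.0, 0.0
    res = stats.kruskal(g0, g1)
    direction = float(np.sign(np.median(g1) - np.median(g0)))
    return float(res.pvalue), direction


def cluster_summary(
    subjects: pd.DataFrame,
    labels: np.ndarray,
    variables: list[str] | None = None,
    fdr: bool = False,
) -> list[ClusterProfile]:
    """Per-cluster profile with ALL / non-faller / faller summaries and
    faller-contrast p-values per variable."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(subjects):
        raise ValueError("labels length must match subject table")
    if variables is None:
        variables = [c for c in subjects.columns if c != "fell"]
    profiles = []
    for c in np.unique(labels):
        sub = subjects.iloc[labels == c]
        n = len(sub)
        if n == 0:
            raise ValueError(f"cluster {c} is empty")
        fallers = sub[sub["fell"] == 1]
        nonfallers = sub[sub["fell"] == 0]
        prevalence = int(round(100.0 * len(fallers) / n))
        rows, pvals = [], {}
        for v in variables:
            rows.append(
                {
                    "variable": v,
                    "all_mean": sub[v].mean(), "all_sd": sub[v].std(ddof=1),
                    "nf_mean": nonfallers[v].mean(), "nf_sd": nonfallers[v].std(ddof=1),
                    "f_mean": fallers[v].mean(), "f_sd": fallers[v].std(ddof=1),
                }
            )
            p, _ = faller_contrast(sub[v].to_numpy(), sub["fell"].to_numpy())
            pvals[v] = p
        pser = pd.Series(pvals)
        if fdr:
            ok = pser.notna()
            ranked = pser[ok].rank(method="first")
            m = ok.sum()
            adj = (pser[ok] * m / ranked).clip(upper=1.0)
            # enforce monotonicity of BH-adjusted values
            order = pser[ok].sort_values().index
            running = 1.0
            for idx in reversed(order):
                running = min(running, adj[idx])
                adj[idx] = running
            pser[ok] = adj
        profiles.append(
            ClusterProfile(int(c), n, prevalence, pd.DataFrame(rows).set_index("variable"), pser)
        )
    return profiles


def profiles_table(profiles: list[ClusterProfile]) -> pd.DataFrame:
    """Flat report: one row per (cluster, variable) with significance stars."""
    rows = []
    for p in profiles:
        for v, r in p.summaries.iterrows():
            pv = p.p_values.get(v, float("nan"))
            rows.append(
                {
                    "cluster": p.cluster, "n": p.n,
                    "fall_prevalence_pct": p.fall_prevalence_pct,
                    "variable": v,
                    "all": f"{r.all_mean:.3g} ± {r.all_sd:.3g}",
                    "non_faller": f"{r.nf_mean:.3g} ± {r.nf_sd:.3g}",
                    "faller": f"{r.f_mean:.3g} ± {r.f_sd:.3g}",
                    "p_value": pv,
                    "significant": bool(pv < 0.05) if np.isfinite(pv) else False,
                }
            )
    return pd.DataFrame(rows)
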