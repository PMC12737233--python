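"""Candidate clustering conditions and the two-stage selection framework.

Stage 1 (gate): a condition is admissible only when the between-cluster
effect size strictly exceeds 0.14 on at least four of the seven key
fall-related parameters (cadence, step speed, stride length, clearance,
swing %, SPPB, TUG).  Normality per cluster (Shapiro-Wilk, alpha 0.05)
decides between one-way ANOVA with eta-squared and Kruskal-Wallis with
epsilon-squared.

Stage 2 (composite): over the admissible conditions, silhouette (from the
precomputed dissimilarity matrix), Davies-Bouldin (from the MDS embedding)
and cluster balance (max size - min size) are max-min normalized, aligned
so larger is better, and summed with equal weights; the highest composite
wins, ties broken by raw silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .config import GateConfig
from .types import DissimilarityMatrix, Embedding

ALGORITHMS = ("kmeans_pp", "kmedoids_pp", "fuzzy_cmeans", "hierarchical")


@dataclass(frozen=True)
class ClusterCondition:
    reducer: str = "pca"  # pca | tsne
    algorithm: str = "kmedoids_pp"
    k: int = 4
    mode: str = "waveform_plus_basic"  # waveform_only | waveform_plus_basic

    def __post_init__(self) -> None:
        if self.reducer not in ("pca", "tsne"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.k not in (3, 4, 5) and self.k < 2:
            raise ValueError("k must be >= 2")

    def label(self) -> str:
        return f"{self.reducer}/{self.algorithm}/k{self.k}/{self.mode}"


@dataclass
class ClusterSolution:
    condition: ClusterCondition
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.condition.k)
        if np.any(sizes == 0):
            raise ValueError("every cluster must be non-empty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.condition.k)


@dataclass
class EffectSizeResult:
    parameter: str
    test_used: str  # anova_eta2 | kruskal_epsilon2
    statistic: float
    effect: float


@dataclass
class QualityIndices:
    silhouette: float
    davies_bouldin: float
    balance: int


@dataclass
class MethodEvaluation:
    condition: ClusterCondition
    gate_passed: bool
    effect_sizes: list = field(default_factory=list)
    indices: QualityIndices | None = None
    composite: float | None = None
    solution: ClusterSolution | None = None


# ---------------------------------------------------------------- algorithms


def _kmedoids_seed(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Careful seeding on a distance matrix: first medoid uniform, the rest
    sampled with probability proportional to squared distance to the nearest
    chosen medoid (k-means++-style)."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = np.min(D[:, medoids], axis=1) ** 2
        d2[medoids] = 0.0
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(remaining)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    return np.array(medoids)


def _kmedoids_once(D: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 200) -> tuple[np.ndarray, float]:
    """Alternating assignment / medoid-swap refinement from one seeding."""
    n = D.shape[0]
    medoids = _kmedoids_seed(D, k, rng)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                # re-seed the collapsed cluster at the worst-served point
                far = np.argmax(np.min(D[:, medoids], axis=1))
                new_medoids[c] = far
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), medoids[labels]].sum())
    return labels, cost


def kmedoids(D: np.ndarray, k: int, seed: int, restarts: int = 10) -> np.ndarray:
    """k-medoids with careful seeding and swap refinement; best of ``restarts``."""
    rng = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(restarts):
        labels, cost = _kmedoids_once(D, k, rng)
        if cost < best_cost and len(np.unique(labels)) == k:
            best_labels, best_cost = labels, cost
    if best_labels is None:  # all restarts collapsed (degenerate D)
        best_labels, _ = _kmedoids_once(D, k, rng)
    return best_labels


def fuzzy_cmeans(
    X: np.ndarray, k: int, seed: int, m: float = 2.0,
    tol: float = 1e-6, max_iter: int = 300, restarts: int = 10,
) -> np.ndarray:
    """Standard fuzzy c-means on coordinates; memberships defuzzified by argmax."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    best_labels, best_obj = None, np.inf
    for _ in range(restarts):
        U = rng.random((n, k))
        U /= U.sum(axis=1, keepdims=True)
        for _ in range(max_iter):
            Um = U ** m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
            d = np.maximum(d, 1e-12)
            inv = d ** (-2.0 / (m - 1.0))
            U_new = inv / inv.sum(axis=1, keepdims=True)
            if np.max(np.abs(U_new - U)) < tol:
                U = U_new
                break
            U = U_new
        obj = float(((U ** m) * d ** 2).sum())
        labels = np.argmax(U, axis=1)
        if len(np.unique(labels)) == k and obj < best_obj:
            best_labels, best_obj = labels, obj
    if best_labels is None:
        best_labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return best_labels


def run_clustering(
    D: DissimilarityMatrix,
    E: Embedding,
    condition: ClusterCondition,
    seed: int = 0,
) -> ClusterSolution:
    """Cluster subjects under one condition.

    kmeans_pp and fuzzy_cmeans operate on the MDS coordinates; kmedoids_pp
    and hierarchical (average linkage cut at k) operate directly on the
    dissimilarity matrix.
    """
    k = condition.k
    if k > D.n:
        raise ValueError(f"k={k} exceeds number of subjects {D.n}")
    if condition.algorithm == "kmeans_pp":
        labels = KMeans(
            n_clusters=k, init="k-means++", n_init=10, random_state=seed
        ).fit_predict(E.coordinates)
    elif condition.algorithm == "fuzzy_cmeans":
        labels = fuzzy_cmeans(E.coordinates, k, seed)
    elif condition.algorithm == "kmedoids_pp":
        labels = kmedoids(D.D, k, seed)
    else:  # hierarchical
        Z = linkage(squareform(D.D, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # canonicalize label ids by first appearance so runs are comparable
    order = {}
    canon = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        canon[i] = order[lab]
    return ClusterSolution(condition, canon)


# ------------------------------------------------------------- gate & indices


def effect_size(
    values: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    parameter: str = "",
) -> EffectSizeResult:
    """Between-cluster effect size of one parameter.

    If Shapiro-Wilk retains normality in every cluster (all clusters having
    at least 3 members), one-way ANOVA is used and eta^2 = SS_between /
    SS_total reported; otherwise Kruskal-Wallis with epsilon^2 = H / (N - 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    N = len(values)

    normal = all(len(g) >= 3 for g in groups)
    if normal:
        for g in groups:
            if np.ptp(g) == 0:  # constant group: shapiro undefined, not normal
                normal = False
                break
            if stats.shapiro(g).pvalue < alpha:
                normal = False
                break
    if normal:
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_total = float(((values - grand) ** 2).sum())
        F = stats.f_oneway(*groups).statistic
        eta2 = ss_between / ss_total if ss_total > 0 else 0.0
        return EffectSizeResult(parameter, "anova_eta2", float(F), float(eta2))
    if np.ptp(values) == 0:
        return EffectSizeResult(parameter, "kruskal_epsilon2", 0.0, 0.0)
    try:
        H = stats.kruskal(*groups).statistic
    except ValueError:  # all values identical
        H = 0.0
    eps2 = H / (N - 1) if N > 1 else 0.0
    return EffectSizeResult(
        parameter, "kruskal_epsilon2", float(H), float(np.clip(eps2, 0.0, 1.0))
    )


def gate_condition(effects: list[EffectSizeResult], gate: GateConfig) -> bool:
    """True iff strictly more than ``effect_threshold`` on >= ``min_passing``
    key parameters."""
    names = {e.parameter for e in effects}
    missing = set(gate.key_parameters) - names
    if missing:
        raise ValueError(f"missing key parameters: {sorted(missing)}")
    n_pass = sum(
        1 for e in effects
        if e.parameter in gate.key_parameters and e.effect > gate.effect_threshold
    )
    return n_pass >= gate.min_passing


def quality_indices(
    D: DissimilarityMatrix, E: Embedding, solution: ClusterSolution
) -> QualityIndices:
    """Silhouette from the precomputed distances, Davies-Bouldin from the
    embedding, and balance = max cluster size - min cluster size."""
    labels = solution.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("quality indices need at least 2 clusters")
    if np.all(np.bincount(labels) == 1):
        raise ValueError("silhouette undefined for singleton-only clustering")
    sil = float(silhouette_score(D.D, labels, metric="precomputed"))
    db = float(davies_bouldin_score(E.coordinates, labels))
    sizes = solution.sizes
    return QualityIndices(sil, db, int(sizes.max() - sizes.min()))


def _maxmin_norm(values: np.ndarray) -> np.ndarray:
    """Max-min normalize; a constant index contributes 0.5 everywhere."""
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.full(len(values), 0.5)
    return (values - lo) / (hi - lo)


def composite_scores(evaluations: list[MethodEvaluation]) -> np.ndarray:
    """Equal-weight composite over gate-passing evaluations: normalized
    silhouette (higher better) + reversed normalized Davies-Bouldin +
    reversed normalized balance."""
    sil = _maxmin_norm(np.array([e.indices.silhouette for e in evaluations]))
    db = _maxmin_norm(np.array([e.indices.davies_bouldin for e in evaluations]))
    bal = _maxmin_norm(np.array([float(e.indices.balance) for e in evaluations]))
    return sil + (1.0 - db) + (1.0 - bal)


def select_best(evaluations: list[MethodEvaluation]) -> MethodEvaluation:
    """Highest composite among gate-passing conditions; ties broken by raw
    silhouette.  Raises if no condition passed the gate."""
    passing = [e for e in evaluations if e.gate_passed and e.indices is not None]
    if not passing:
        raise ValueError("no admissible method: every condition failed the effect-size gate")
    scores = composite_scores(passing)
    for e, s in zip(passing, scores):
        e.composite = float(s)
    best = max(passing, key=lambda e: (e.composite, e.indices.silhouette))
    return best


def evaluate_conditions(
    D_by_mode: dict,
    E_by_mode: dict,
    features: pd.DataFrame,
    gate: GateConfig,
    conditions: list[ClusterCondition],
    seed: int = 0,
) -> list[MethodEvaluation]:
    """Run every candidate condition, apply the effect-size gate, and compute
    quality indices for the admissible ones."""
    out = []
    for cond in conditions:
        D, E = D_by_mode[cond.mode], E_by_mode[cond.mode]
        sol = run_clustering(D, E, cond, seed=seed)
        effects = [
            effect_size(
                features[p].to_numpy(dtype=float), sol.labels,
                alpha=gate.normality_alpha, parameter=p,
            )
            for p in gate.key_parameters
        ]
        passed = gate_condition(effects, gate)
        ev = MethodEvaluation(cond, passed, effects, solution=sol)
        if passed:
            ev.indices = quality_indices(D, E, sol)
        out.append(ev)
    return out


def evaluations_table(evaluations: list[MethodEvaluation]) -> pd.DataFrame:
    """Flat CSV-ready view of the method search."""
    rows = []
    for e in evaluations:
        row = {
            "reducer": e.condition.reducer,
            "algorithm": e.condition.algorithm,
            "k": e.condition.k,
            "mode": e.condition.mode,
            "gate_passed": e.gate_passed,
        }
        for es in e.effect_sizes:
            row[f"effect_{es.parameter}"] = es.effect
            row[f"test_{es.parameter}"] = es.test_used
        if e.indices is not None:
            row["silhouette"] = e.indices.silhouette
            row["davies_bouldin"] = e.indices.davies_bouldin
            row["balance"] = e.indices.balance
        row["composite"] = e.composite
        rows.append(row)
    return pd.DataFrame(rows)
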