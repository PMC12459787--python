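"""Pairwise performance benefits, k-means clustering and the gap statistic.

The network-information analysis: a model is trained on every pair of
bilateral gray regions (for delta, with the non-gray regions always
included), and each pair's held-out performance minus its best single
component gives the pairwise *benefit* — positive where the two regions
carry complementary information, near zero or negative where redundant.
Each region's row of the benefit matrix is its benefit profile; k-means
clusters these profiles, and the gap statistic (uniform reference in a
PCA-aligned box) selects the number of clusters, with k = 1 meaning "no
suitable clustering". A supplementary comparison clusters plain BOLD
correlation matrices with the same machinery to show the benefit
structure is not ordinary functional connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .data import InvalidDataError
from .qc import PreparedDataset
from .ridge import LosoEvaluator
from .windows import assemble_design

__all__ = [
    "PairPerformanceMatrix", "BenefitMatrix", "ClusterSolution", "GapResult",
    "pairwise_eval", "pair_benefit", "kmeans_cluster", "gap_statistic",
    "cluster_pair_summary", "bold_correlation_clustering",
]


@dataclass
class PairPerformanceMatrix:
    """Symmetric LOSO mean r for every region pair; diagonal = singles."""

    labels: list[str]
    values: np.ndarray                 # (n, n)
    r_subjects: np.ndarray | None = None  # (n, n, n_subjects) per-subject r

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InvalidDataError("pair performance matrix must be symmetric")


@dataclass
class BenefitMatrix:
    """benefit(i, j) = r_pair(i, j) - max(r_single(i), r_single(j))."""

    labels: list[str]
    values: np.ndarray

    def profiles(self) -> np.ndarray:
        """Row benefit profiles for clustering; diagonal fixed at 0."""
        P = self.values.copy()
        np.fill_diagonal(P, 0.0)
        return P


@dataclass
class ClusterSolution:
    labels: dict[str, int]
    k: int
    dispersion: float  # within-cluster sum of squared distances to centroids

    def assignment(self, order: list[str]) -> np.ndarray:
        return np.array([self.labels[name] for name in order])


@dataclass
class GapResult:
    ks: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w_data: np.ndarray
    log_w_ref_mean: np.ndarray
    chosen_k: int

    @property
    def no_clustering(self) -> bool:
        return self.chosen_k == 1


# ---------------------------------------------------------------------------

def pairwise_eval(prepared: PreparedDataset, band: str,
                  evaluator: LosoEvaluator | None = None,
                  groups: dict[str, list[str]] | None = None,
                  **evaluator_kwargs) -> PairPerformanceMatrix:
    """LOSO mean r for every unordered pair of bilateral gray regions.

    For delta, every model (singles and pairs) additionally includes all
    non-gray regions. One cached evaluator serves all O(n^2) models.
    """
    atlas = prepared.atlas
    if groups is None:
        groups = atlas.gray_bilateral_groups()
    labels = list(groups)
    extra = atlas.nongray_regions if band == "delta" else []
    if evaluator is None:
        design = assemble_design(prepared, None, band)
        evaluator = LosoEvaluator(design, **evaluator_kwargs)
    n = len(labels)
    n_subj = None
    vals = np.full((n, n), np.nan)
    per_subj = None
    for i, a in enumerate(labels):
        res = evaluator.loso(list(groups[a]) + extra, condition=a)
        rv = np.array([f.mean_r for f in res])
        if per_subj is None:
            n_subj = len(rv)
            per_subj = np.full((n, n, n_subj), np.nan)
        vals[i, i] = np.nanmean(rv)
        per_subj[i, i] = rv
    for i in range(n):
        for j in range(i + 1, n):
            regions = list(groups[labels[i]]) + list(groups[labels[j]]) + extra
            res = evaluator.loso(regions, condition=f"{labels[i]}+{labels[j]}")
            rv = np.array([f.mean_r for f in res])
            vals[i, j] = vals[j, i] = np.nanmean(rv)
            per_subj[i, j] = per_subj[j, i] = rv
    return PairPerformanceMatrix(labels=labels, values=vals, r_subjects=per_subj)


def pair_benefit(pairs: PairPerformanceMatrix) -> BenefitMatrix:
    """Performance gain of each pair over its best individual component."""
    v = pairs.values
    singles = np.diag(v)
    best = np.maximum(singles[:, None], singles[None, :])
    benefit = v - best
    np.fill_diagonal(benefit, 0.0)
    return BenefitMatrix(labels=list(pairs.labels), values=benefit)


def kmeans_cluster(benefit: BenefitMatrix | np.ndarray, k: int,
                   n_restarts: int = 50,
                   rng: np.random.Generator | None = None,
                   labels: list[str] | None = None) -> ClusterSolution:
    """k-means on benefit profiles; best of n_restarts by dispersion."""
    if isinstance(benefit, BenefitMatrix):
        points = benefit.profiles()
        labels = benefit.labels
    else:
        points = np.asarray(benefit, float)
        if labels is None:
            labels = [str(i) for i in range(len(points))]
    n = len(points)
    if k < 1 or k > n:
        raise InvalidDataError("k must be between 1 and the number of regions")
    rng = rng or np.random.default_rng(0)
    if k == 1:
        center = points.mean(axis=0)
        w = float(np.sum((points - center) ** 2))
        return ClusterSolution({name: 0 for name in labels}, 1, w)
    seed = int(rng.integers(2 ** 31 - 1))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(points)
    return ClusterSolution(
        {name: int(c) for name, c in zip(labels, km.labels_)},
        k, float(km.inertia_))


def _dispersion(points: np.ndarray, k: int, n_restarts: int,
                rng: np.random.Generator) -> float:
    if k == 1:
        c = points.mean(axis=0)
        return float(np.sum((points - c) ** 2))
    seed = int(rng.integers(2 ** 31 - 1))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(points)
    return float(km.inertia_)


def gap_statistic(points: np.ndarray, k_range: range | list[int] | None = None,
                  B: int = 100, rng: np.random.Generator | None = None,
                  n_restarts: int = 10) -> GapResult:
    """Tibshirani gap statistic with a PCA-aligned uniform-box reference.

    Gap(k) = mean_b log W*_kb - log W_k, SE(k) = sd_b(log W*_kb) * sqrt(1 + 1/B).
    Chosen k is the smallest satisfying Gap(k) >= Gap(k+1) - SE(k+1);
    k = 1 means the data do not support clustering.
    """
    points = np.asarray(points, float)
    n = len(points)
    if k_range is None:
        k_range = range(1, min(n, 7))
    ks = np.array(sorted(k_range))
    if ks[0] != 1:
        raise InvalidDataError("k_range must start at 1")
    ks = ks[ks <= n]  # cannot place more centroids than points
    if B < 10:
        raise InvalidDataError("B must be >= 10")
    rng = rng or np.random.default_rng(0)

    center = points.mean(axis=0)
    Xc = points - center
    if np.allclose(Xc, 0):
        return GapResult(ks, np.zeros(len(ks)), np.zeros(len(ks)),
                         np.zeros(len(ks)), np.zeros(len(ks)), 1)
    # principal-component frame for the reference box
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    log_w = np.array([np.log(max(_dispersion(points, k, n_restarts, rng),
                                 np.finfo(float).tiny)) for k in ks])
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        Zp = rng.uniform(lo, hi, size=Xp.shape)
        Z = Zp @ Vt + center
        for j, k in enumerate(ks):
            log_w_ref[b, j] = np.log(max(_dispersion(Z, k, n_restarts, rng),
                                         np.finfo(float).tiny))
    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)

    chosen = int(ks[-1])
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            chosen = int(ks[j])
            break
    return GapResult(ks=ks, gap=gap, se=se, log_w_data=log_w,
                     log_w_ref_mean=log_w_ref.mean(axis=0), chosen_k=chosen)


def cluster_pair_summary(benefit: BenefitMatrix, solution: ClusterSolution,
                         ci: float = 95.0) -> pd.DataFrame:
    """Mean benefit and t-based CI for every unordered cluster pair.

    Self-pairs use the within-cluster upper-triangle entries; a singleton
    cluster's self-pair has no entries and is reported as missing.
    """
    assign = solution.assignment(benefit.labels)
    clusters = sorted(set(assign.tolist()))
    V = benefit.values
    rows = []
    for ai, a in enumerate(clusters):
        for b in clusters[ai:]:
            ia = np.flatnonzero(assign == a)
            ib = np.flatnonzero(assign == b)
            if a == b:
                entries = np.array([V[i, j] for k, i in enumerate(ia)
                                    for j in ia[k + 1:]])
            else:
                entries = V[np.ix_(ia, ib)].ravel()
            if len(entries) == 0:
                rows.append((a, b, np.nan, np.nan, np.nan, 0))
                continue
            m = float(np.mean(entries))
            if len(entries) > 1 and np.std(entries, ddof=1) > 0:
                half = stats.t.ppf(0.5 + ci / 200.0, len(entries) - 1) \
                    * stats.sem(entries)
            else:
                half = 0.0
            rows.append((a, b, m, m - half, m + half, len(entries)))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "mean_benefit",
                                       "ci_lo", "ci_hi", "n_entries"])


def bold_correlation_clustering(prepared: PreparedDataset,
                                benefit_solution: ClusterSolution | None = None,
                                k_range=None, B: int = 100,
                                rng: np.random.Generator | None = None,
                                n_restarts: int = 10,
                                groups: dict[str, list[str]] | None = None):
    """Cluster region-by-region BOLD correlations with the same machinery.

    Ordinary functional connectivity: Pearson correlation of concatenated
    cleaned BOLD between bilateral-group mean time series, clustered by
    the same k-means + gap-statistic pipeline. Returns (solution,
    gap_result, correlation matrix, ARI vs the benefit-based solution or
    None).
    """
    rng = rng or np.random.default_rng(0)
    atlas = prepared.atlas
    if groups is None:
        groups = atlas.gray_bilateral_groups()
    labels = list(groups)
    pos = {name: i for i, name in enumerate(prepared.region_labels)}
    stacked = np.vstack([seg.fmri for seg in prepared.segments])
    series = np.column_stack([
        stacked[:, [pos[r] for r in groups[g]]].mean(axis=1) for g in labels])
    corr = np.corrcoef(series.T)
    gap = gap_statistic(corr, k_range=k_range, B=B, rng=rng,
                        n_restarts=n_restarts)
    solution = kmeans_cluster(corr, gap.chosen_k, n_restarts=max(n_restarts, 10),
                              rng=rng, labels=labels)
    ari = None
    if benefit_solution is not None:
        a = benefit_solution.assignment(labels)
        b = solution.assignment(labels)
        ari = float(adjusted_rand_score(a, b))
    return solution, gap, corr, ari
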