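"""Iterative low-weight-region removal (spatial-scale analysis).

After training on all regions, each region's importance is the sum of
its squared beta weights across the 60 TR offsets (averaged over LOSO
folds and seed repeats). Regions below the bottom 10% of that
distribution are removed and the model is retrained, repeating until 5
regions remain. Per-iteration performance is compared against the
full-region model with paired two-tailed t-tests, Benjamini-Hochberg
corrected across iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import InvalidDataError
from .qc import PreparedDataset
from .ridge import LinearModel, LosoEvaluator
from .windows import assemble_design

__all__ = ["PruningTrace", "region_weight_norms", "iterative_prune", "bh_correct"]


@dataclass
class PruningIteration:
    regions: list[str]
    r_values: np.ndarray          # per-subject mean r
    norms: dict[str, float]       # region -> mean sum of squared weights
    p_vs_full: float = float("nan")

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_values))


@dataclass
class PruningTrace:
    iterations: list[PruningIteration] = field(default_factory=list)
    p_adjusted: np.ndarray | None = None
    significant: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        rows = [(i, len(it.regions), it.mean_r, it.p_vs_full)
                for i, it in enumerate(self.iterations)]
        df = pd.DataFrame(rows, columns=["iteration", "n_regions", "mean_r", "p"])
        if self.p_adjusted is not None:
            df["p_adj"] = self.p_adjusted
            df["significant"] = self.significant
        return df

    @property
    def peak_iteration(self) -> int:
        return int(np.nanargmax([it.mean_r for it in self.iterations]))


def region_weight_norms(model: LinearModel) -> dict[str, float]:
    """Sum of squared beta weights over each region's 60 columns."""
    if model.region_subset is None:
        raise InvalidDataError("model carries no region subset / column map")
    w = model.weights
    L = model.window_len
    return {r: float(np.sum(w[i * L: (i + 1) * L] ** 2))
            for i, r in enumerate(model.region_subset)}


def bh_correct(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control: (flags, adjusted p)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidDataError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([], dtype=bool), np.array([])
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, p_adj


def _n_to_drop(n_regions: int, drop_fraction: float) -> int:
    return max(1, math.floor(drop_fraction * n_regions))


def iterative_prune(prepared: PreparedDataset, band: str,
                    drop_fraction: float = 0.10, min_regions: int = 5,
                    alpha_level: float = 0.05,
                    reoptimize_lambda: bool = False,
                    evaluator_kwargs: dict | None = None) -> PruningTrace:
    """Remove the lowest-weight regions until ``min_regions`` remain.

    Weight norms are averaged over LOSO folds and seed repeats before
    thresholding; ties at the cutoff are broken by removing the lowest
    norms first. By default the per-fold lambda chosen on the full model
    is reused in later iterations (lambda choices are stable across
    nested region sets); pass ``reoptimize_lambda=True`` to re-run the
    grid search at every iteration.
    """
    evaluator_kwargs = dict(evaluator_kwargs or {})
    design = assemble_design(prepared, None, band)
    ev = LosoEvaluator(design, **evaluator_kwargs)
    regions = list(prepared.region_labels)
    # a handful of held-out windows yields meaningless (even exactly +/-1) r
    usable = [s for s in ev.subjects if (design.groups == s).sum() >= 30]

    trace = PruningTrace()
    fixed_lams: dict[str, list[float]] | None = None
    full_r = None
    while True:
        results = []
        subset = regions if len(regions) < len(prepared.region_labels) else None
        shared = ev._prepare_subset(subset)
        for subj in usable:
            kwargs = {}
            if fixed_lams is not None and not reoptimize_lambda:
                kwargs["fixed_lambdas"] = fixed_lams[subj]
            results.append(ev.evaluate_subject(
                subj, subset, condition=f"n={len(regions)}",
                return_models=True, _prepared=shared, **kwargs))
        if fixed_lams is None:
            fixed_lams = {f.held_out: list(f.lambdas) for f in results}
        r_values = np.array([f.mean_r for f in results])
        norm_acc: dict[str, list[float]] = {r: [] for r in regions}
        for f in results:
            for model in f.models:
                for r, v in region_weight_norms(model).items():
                    norm_acc[r].append(v)
        norms = {r: float(np.mean(v)) for r, v in norm_acc.items()}
        it = PruningIteration(regions=list(regions), r_values=r_values, norms=norms)
        if full_r is None:
            full_r = r_values
            it.p_vs_full = 1.0
        elif np.allclose(r_values, full_r):
            it.p_vs_full = 1.0
        else:
            it.p_vs_full = float(stats.ttest_rel(r_values, full_r).pvalue)
        trace.iterations.append(it)
        if len(regions) <= min_regions:
            break
        k = min(_n_to_drop(len(regions), drop_fraction),
                len(regions) - min_regions)
        order = sorted(regions, key=lambda r: norms[r])
        drop = set(order[:k])
        regions = [r for r in regions if r not in drop]

    pvals = np.array([it.p_vs_full for it in trace.iterations])
    flags, p_adj = bh_correct(pvals, alpha_level)
    trace.p_adjusted = p_adj
    trace.significant = flags
    return trace
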