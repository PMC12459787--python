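"""Anatomical-group comparisons and single-region predictive maps.

Which regions carry information about the EEG target? The model is
evaluated on anatomically defined subsets (cortex, subcortex, non-gray
matter, everything, and a temporal-shuffle control), compared with a
repeated-measures ANOVA + Tukey HSD, and then on each bilateral
gray-matter region alone. For alpha the single-region baseline is the
shuffled control; for delta — whose predictive information rides partly
on systemic physiology visible in ventricles and white matter — each
single-region model additionally includes the non-gray regions, and the
baseline is the non-gray-only model, so a region is called informative
only if it adds to the systemic signal. A bootstrap that shuffles region
labels within subject checks that the ordered map could not arise from
noise ordering alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import InvalidDataError
from .qc import PreparedDataset
from .ridge import FoldResult, LosoEvaluator, null_loso, shuffle_control
from .windows import assemble_design

__all__ = [
    "ConditionResult", "RegionMap", "BootstrapOrderResult",
    "condition_eval", "anova_tukey", "single_region_map",
    "bootstrap_order_control",
]

CONDITIONS = ("brainwide", "cortical", "subcortical", "nongray", "control")


@dataclass
class ConditionResult:
    condition: str
    subjects: list[str]
    r_values: np.ndarray  # per-subject mean r

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_values))


@dataclass
class RegionMap:
    """Per bilateral-region performance with baseline comparison."""

    table: pd.DataFrame            # region, mean_r, p, significant
    r_matrix: np.ndarray           # regions x subjects
    subjects: list[str]
    baseline_r: np.ndarray         # per-subject baseline r
    band: str


@dataclass
class BootstrapOrderResult:
    real_line: np.ndarray
    null_mean_line: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    real_slope: float
    null_slopes: np.ndarray
    outside: bool


def _per_subject_r(results: list[FoldResult]) -> tuple[list[str], np.ndarray]:
    return [f.held_out for f in results], np.array([f.mean_r for f in results])


def condition_eval(prepared: PreparedDataset, band: str,
                   rng: np.random.Generator | None = None,
                   n_null_shuffles: int | None = None,
                   **evaluator_kwargs) -> list[ConditionResult]:
    """LOSO performance for cortex / subcortex / non-gray / brainwide /
    shuffled-control region sets.

    The control condition averages per-subject r over independent
    temporal shuffles (default: as many as there are seed repeats)."""
    rng = rng or np.random.default_rng(0)
    atlas = prepared.atlas
    design = assemble_design(prepared, None, band)
    ev = LosoEvaluator(design, **evaluator_kwargs)
    out = []
    subsets = {
        "brainwide": None,
        "cortical": atlas.regions_of_class("cortical"),
        "subcortical": atlas.regions_of_class("subcortical"),
        "nongray": atlas.regions_of_class("nongray"),
    }
    for cond, regions in subsets.items():
        if regions is not None and not regions:
            continue
        subjects, rvals = _per_subject_r(ev.loso(regions, condition=cond))
        out.append(ConditionResult(cond, subjects, rvals))
    if n_null_shuffles is None:
        n_null_shuffles = evaluator_kwargs.get("n_repeats", 10)
    rvals = null_loso(prepared, band, n_null_shuffles, rng, **evaluator_kwargs)
    out.append(ConditionResult("control", subjects, rvals))
    return out


def anova_tukey(results: list[ConditionResult]) -> tuple[dict, pd.DataFrame]:
    """Repeated-measures ANOVA (subject as blocking factor) + Tukey HSD.

    Tukey's studentized-range test is computed from the ANOVA residual
    mean square, i.e. the subject-by-condition interaction, matching a
    design with subject as a random effect. Returns (anova dict, pairwise
    table with adjusted p per condition pair).
    """
    if len(results) < 2:
        raise InvalidDataError("need at least two conditions")
    subjects = results[0].subjects
    for res in results:
        if res.subjects != subjects or len(res.r_values) != len(subjects):
            raise InvalidDataError("conditions must share a balanced subject set")
    if len(subjects) < 3:
        raise InvalidDataError("need at least three subjects")
    Y = np.column_stack([res.r_values for res in results])  # subjects x k
    n, k = Y.shape
    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = Y - subj_means[:, None] - cond_means[None, :] + grand
    ss_err = float(np.sum(resid ** 2))
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    F = ms_cond / ms_err if ms_err > 0 else np.inf
    anova = {"F": float(F), "df": (df_cond, df_err),
             "p": float(stats.f.sf(F, df_cond, df_err)) if np.isfinite(F) else 0.0}
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = cond_means[i] - cond_means[j]
            if ms_err > 0:
                q = abs(diff) / np.sqrt(ms_err / n)
                p = float(stats.studentized_range.sf(q, k, df_err))
            else:
                q, p = 0.0, 1.0
            rows.append((results[i].condition, results[j].condition,
                         float(diff), float(q), min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["cond_a", "cond_b", "mean_diff", "q", "p_adj"])
    return anova, table


def single_region_map(prepared: PreparedDataset, band: str,
                      rng: np.random.Generator | None = None,
                      alpha_level: float = 0.05, bh: bool = False,
                      evaluator: LosoEvaluator | None = None,
                      **evaluator_kwargs) -> RegionMap:
    """LOSO performance of each bilateral gray region on its own.

    delta models include the non-gray regions alongside the region under
    test, and are compared against the non-gray-only baseline; alpha
    models contain only the region and are compared against the
    temporal-shuffle control.
    """
    rng = rng or np.random.default_rng(0)
    n_null = evaluator_kwargs.pop("n_null_shuffles", None)
    atlas = prepared.atlas
    groups = atlas.gray_bilateral_groups()
    if evaluator is None:
        design = assemble_design(prepared, None, band)
        evaluator = LosoEvaluator(design, **evaluator_kwargs)
    nongray = atlas.nongray_regions if band == "delta" else []

    rows = []
    r_cols = []
    subjects = None
    for gname, members in groups.items():
        regions = list(members) + list(nongray)
        subs, rvals = _per_subject_r(evaluator.loso(regions, condition=gname))
        subjects = subs if subjects is None else subjects
        r_cols.append(rvals)
        rows.append(gname)
    r_matrix = np.vstack(r_cols)

    if band == "delta" and nongray:
        _, baseline = _per_subject_r(evaluator.loso(list(nongray), condition="nongray"))
    else:
        n_null = n_null or evaluator_kwargs.get("n_repeats", 10)
        baseline = null_loso(prepared, band, n_null, rng, **evaluator_kwargs)

    pvals = []
    for i in range(len(rows)):
        if np.allclose(r_matrix[i], baseline):
            pvals.append(1.0)
        else:
            pvals.append(float(stats.ttest_rel(r_matrix[i], baseline).pvalue))
    pvals = np.array(pvals)
    if bh:
        from .pruning import bh_correct
        flags, p_adj = bh_correct(pvals, alpha_level)
        table = pd.DataFrame({"region": rows, "mean_r": r_matrix.mean(axis=1),
                              "p": pvals, "p_adj": p_adj, "significant": flags})
    else:
        table = pd.DataFrame({"region": rows, "mean_r": r_matrix.mean(axis=1),
                              "p": pvals,
                              "significant": (pvals < alpha_level)
                              & (r_matrix.mean(axis=1) > baseline.mean())})
    return RegionMap(table=table, r_matrix=r_matrix, subjects=subjects,
                     baseline_r=baseline, band=band)


def bootstrap_order_control(r_matrix: np.ndarray, n_boot: int = 1000,
                            ci: float = 95.0,
                            rng: np.random.Generator | None = None
                            ) -> BootstrapOrderResult:
    """Can the ordered region map be explained by ordering of noise?

    Region labels are shuffled within each subject; region means are
    ordered and a line is fit to the ordered means (OLS against rank).
    The real ordered-means line is compared with the null distribution of
    fitted lines; the map is called significant when the real slope falls
    outside the central ``ci``% of null slopes. Pointwise envelopes of
    the null lines are returned for display.
    """
    r_matrix = np.asarray(r_matrix, float)
    if r_matrix.ndim != 2 or min(r_matrix.shape) < 2:
        raise InvalidDataError("need >= 2 regions and >= 2 subjects")
    rng = rng or np.random.default_rng(0)
    R, S = r_matrix.shape
    rank = np.arange(R, dtype=float)
    rank_c = rank - rank.mean()
    denom = float(rank_c @ rank_c)

    def fit_line(ordered: np.ndarray) -> tuple[np.ndarray, float]:
        slope = (rank_c @ ordered) / denom
        intercept = ordered.mean() - slope * rank.mean()
        return intercept + slope * rank, float(slope)

    real_sorted = np.sort(r_matrix.mean(axis=1))
    real_line, real_slope = fit_line(real_sorted)

    # shuffle region labels independently within each subject, all draws at once
    tiled = np.broadcast_to(r_matrix[:, :, None], (R, S, n_boot)).copy()
    rng.permuted(tiled, axis=0, out=tiled)
    null_means = np.sort(tiled.mean(axis=1), axis=0)        # (R, n_boot)
    null_slopes = (rank_c @ null_means) / denom             # (n_boot,)
    null_inter = null_means.mean(axis=0) - null_slopes * rank.mean()
    null_lines = null_inter[None, :] + np.outer(rank, null_slopes)

    a = (100.0 - ci) / 2.0
    lo_s, hi_s = np.percentile(null_slopes, [a, 100.0 - a])
    outside = bool(real_slope < lo_s or real_slope > hi_s)
    return BootstrapOrderResult(
        real_line=real_line,
        null_mean_line=null_lines.mean(axis=1),
        envelope_lo=np.percentile(null_lines, a, axis=1),
        envelope_hi=np.percentile(null_lines, 100.0 - a, axis=1),
        real_slope=real_slope, null_slopes=null_slopes, outside=outside)
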