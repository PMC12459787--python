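"""L2-regularized linear decoding with leave-one-subject-out evaluation.

The model minimizes ||y - X beta - b||^2 + lambda ||beta||^2 with an
unpenalized intercept. Lambda is chosen per training fold by grid search:
each of the 30 candidates is scored by mean validation MSE over a fresh
5-fold partition of the training data (the held-out subject never
participates). Because adjacent predictor windows share 59 of 60 TRs,
cross-validation folds partition contiguous *blocks* of windows rather
than individual windows; observation-level folds would place near-copies
of validation rows in the training set and make every lambda look alike.

Solvers: the normal-equations (primal) form via Cholesky when the
feature count allows, and the kernel (dual) form when features outnumber
windows (e.g. all 84 regions at small n). Both match the closed-form
ridge solution; an SGD solver is available for cross-checking. Block
Gram/kernel matrices are cached so that evaluating many region subsets
(single regions, pairs, pruned sets) reuses one expensive pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .data import InvalidDataError
from .qc import PreparedDataset, Segment
from .windows import WindowDataset

__all__ = [
    "LinearModel", "FoldResult", "lambda_grid", "fit_ridge",
    "optimize_lambda", "LosoEvaluator", "evaluate_fold", "loso_evaluate",
    "shuffle_control", "mean_r",
]


@dataclass
class LinearModel:
    """Fitted ridge model: one weight per (region, TR offset) column."""

    weights: np.ndarray
    intercept: float
    lam: float
    region_subset: list[str] | None = None
    window_len: int = 60

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept

    def column_map(self) -> dict[tuple[str, int], int]:
        """(region, TR offset) -> column index."""
        if self.region_subset is None:
            raise InvalidDataError("model has no region subset recorded")
        return {(r, t): i * self.window_len + t
                for i, r in enumerate(self.region_subset)
                for t in range(self.window_len)}


@dataclass
class FoldResult:
    """Held-out performance of one LOSO fold over repeated seeds."""

    held_out: str
    r_per_seed: list[float]
    lambdas: list[float]
    condition: str = ""
    models: list[LinearModel] = field(default_factory=list, repr=False)

    @property
    def mean_r(self) -> float:
        vals = [r for r in self.r_per_seed if np.isfinite(r)]
        return float(np.mean(vals)) if vals else float("nan")


def mean_r(results: list[FoldResult]) -> float:
    return float(np.nanmean([f.mean_r for f in results]))


def lambda_grid(n_train: int, n_candidates: int = 30) -> np.ndarray:
    """Log-spaced per-observation grid [1e-6, 1e3], scaled by n to the
    absolute-lambda objective."""
    return np.geomspace(1e-6, 1e3, n_candidates) * n_train


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant predictions or targets; r undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# direct solvers

def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float,
              solver: str = "auto", region_subset: list[str] | None = None,
              window_len: int = 60, sgd_seed: int = 0) -> LinearModel:
    """Exact ridge fit with unpenalized intercept.

    ``solver='auto'`` picks the primal normal equations when p <= n and the
    dual (kernel) form otherwise; 'sgd' uses stochastic gradient descent on
    the same objective (cross-check only, approximate).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidDataError("non-finite values in X or y")
    if X.shape[0] < 2:
        raise InvalidDataError("need at least 2 rows")
    if lam < 0:
        raise InvalidDataError("lambda must be nonnegative")
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    if solver == "sgd":
        from sklearn.linear_model import SGDRegressor
        sgd = SGDRegressor(penalty="l2", alpha=lam / n, fit_intercept=False,
                           max_iter=2000, tol=1e-8, random_state=sgd_seed)
        sgd.fit(Xc, yc)
        beta = sgd.coef_
    elif lam == 0:
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    elif solver == "dual" or (solver == "auto" and p > n):
        K = Xc @ Xc.T
        K.flat[:: n + 1] += lam
        alpha = sla.solve(K, yc, assume_a="pos")
        beta = Xc.T @ alpha
    else:
        G = Xc.T @ Xc
        G.flat[:: p + 1] += lam
        beta = sla.solve(G, Xc.T @ yc, assume_a="pos")
    intercept = ym - float(xm @ beta)
    return LinearModel(weights=beta, intercept=intercept, lam=lam,
                       region_subset=region_subset, window_len=window_len)


# ---------------------------------------------------------------------------
# block bookkeeping

def _contiguous_blocks(n: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _partition_blocks(n_blocks: int, n_folds: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    order = rng.permutation(n_blocks)
    folds = [np.sort(order[k::n_folds]) for k in range(min(n_folds, n_blocks))]
    return folds


class _PrimalGrams:
    """Per-block Gram statistics over the full column set."""

    def __init__(self, X: np.ndarray, y: np.ndarray, slices: list[slice]):
        self.slices = slices
        B = len(slices)
        p = X.shape[1]
        self.G = np.empty((B, p, p))
        self.c = np.empty((B, p))
        self.s = np.empty((B, p))
        self.ysum = np.empty(B)
        self.n = np.empty(B, dtype=int)
        for b, sl in enumerate(slices):
            Xb = X[sl]
            yb = y[sl]
            self.G[b] = Xb.T @ Xb
            self.c[b] = Xb.T @ yb
            self.s[b] = Xb.sum(axis=0)
            self.ysum[b] = yb.sum()
            self.n[b] = Xb.shape[0]

    def subset(self, cols: np.ndarray) -> "_PrimalGrams":
        sub = object.__new__(_PrimalGrams)
        sub.slices = self.slices
        sub.G = np.ascontiguousarray(self.G[:, cols[:, None], cols[None, :]])
        sub.c = self.c[:, cols]
        sub.s = self.s[:, cols]
        sub.ysum = self.ysum
        sub.n = self.n
        return sub


def _posv(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve via one LAPACK call (A is overwritten)."""
    _, x, info = sla.lapack.dposv(A, b, lower=0, overwrite_a=0, overwrite_b=0)
    if info != 0:
        return np.linalg.lstsq(A, b, rcond=None)[0]
    return x


def _solve_centered(G_sum, c_sum, s_sum, ysum, n, lam):
    """Solve ridge from accumulated (uncentered) Gram statistics."""
    xm = s_sum / n
    ym = ysum / n
    Gc = G_sum - np.outer(s_sum, xm)
    bc = c_sum - s_sum * ym
    p = len(bc)
    Gc.flat[:: p + 1] += lam
    beta = _posv(Gc, bc)
    return beta, ym - float(xm @ beta)


def _grid_search_primal(grams: _PrimalGrams, X: np.ndarray, y: np.ndarray,
                        block_ids: np.ndarray, lams: np.ndarray,
                        n_folds: int, rng: np.random.Generator) -> float:
    """Pick lambda by n-fold CV over blocks, fresh partition per candidate.

    All (candidate, fold) ridge systems are assembled from block Gram
    statistics and solved in one batched LAPACK call; validation MSE uses
    per-block residual sums so no per-fold Python loop remains.
    """
    nc = len(lams)
    B = len(block_ids)
    n_folds = min(n_folds, B)
    Gb = grams.G[block_ids]
    cb = grams.c[block_ids]
    sb = grams.s[block_ids]
    yb = grams.ysum[block_ids]
    nb = grams.n[block_ids].astype(float)
    G_tot = Gb.sum(axis=0)
    c_tot = cb.sum(axis=0)
    s_tot = sb.sum(axis=0)
    y_tot = yb.sum()
    n_tot = nb.sum()

    # fresh partition per candidate -> validation membership (T, B)
    T = nc * n_folds
    M = np.zeros((T, B))
    for ci in range(nc):
        for fi, fold in enumerate(_partition_blocks(B, n_folds, rng)):
            M[ci * n_folds + fi, fold] = 1.0

    p = G_tot.shape[0]
    diag = np.arange(p)
    starts = np.array([sl.start for sl in grams.slices])
    lam_per_combo = np.repeat(lams, n_folds)
    mse = np.empty(T)
    # chunk the (candidate, fold) batch to bound the (chunk, p, p) workspace
    chunk = max(n_folds, int(3e8 / (8 * p * p)) // n_folds * n_folds or n_folds)
    for t0 in range(0, T, chunk):
        t1 = min(t0 + chunk, T)
        Mc = M[t0:t1]
        Gc = G_tot[None] - np.tensordot(Mc, Gb, axes=(1, 0))  # (c, p, p)
        strn = s_tot[None] - Mc @ sb
        ntr = n_tot - Mc @ nb
        xm = strn / ntr[:, None]
        ym = (y_tot - Mc @ yb) / ntr
        Gc -= strn[:, :, None] * xm[:, None, :]
        bc = (c_tot[None] - Mc @ cb) - strn * ym[:, None]
        Gc[:, diag, diag] += lam_per_combo[t0:t1, None]
        try:
            # single precision for CV scoring only: candidate ranking is
            # driven by MSE differences far above fp32 resolution
            beta = np.linalg.solve(Gc.astype(np.float32),
                                   bc[:, :, None].astype(np.float32)
                                   )[:, :, 0].astype(np.float64)
        except np.linalg.LinAlgError:
            beta = np.stack([_posv(Gc[t], bc[t]) for t in range(t1 - t0)])
        b0 = ym - np.einsum("ti,ti->t", xm, beta)
        resid2 = (y[:, None] - X @ beta.T - b0[None, :]) ** 2
        block_sse = np.add.reduceat(resid2, starts, axis=0)
        M_all = np.zeros((t1 - t0, len(grams.slices)))
        M_all[:, block_ids] = Mc
        mse[t0:t1] = np.einsum("tb,bt->t", M_all, block_sse) / (Mc @ nb)
    score = mse.reshape(nc, n_folds).mean(axis=1)
    return float(lams[int(np.argmin(score))])


def optimize_lambda(X: np.ndarray, y: np.ndarray, n_folds: int = 5,
                    n_candidates: int = 30, rng: np.random.Generator | None = None,
                    n_blocks: int | None = None) -> float:
    """Grid-search lambda with a fresh block 5-fold partition per candidate.

    Deterministic given ``rng``. The candidate budget (default 30) mirrors
    the number of hyperparameter evaluations in the training protocol.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < n_folds:
        raise InvalidDataError("need at least n_folds rows")
    rng = rng or np.random.default_rng(0)
    if n_blocks is None:
        n_blocks = min(4 * n_folds, n)
    n_blocks = max(n_blocks, n_folds)
    slices = _contiguous_blocks(n, n_blocks)
    grams = _PrimalGrams(X, y, slices)
    lams = lambda_grid(n, n_candidates)
    return _grid_search_primal(grams, X, y, np.arange(len(slices)), lams,
                               n_folds, rng)


# ---------------------------------------------------------------------------
# LOSO evaluation engine

class LosoEvaluator:
    """Leave-one-subject-out evaluation with cached Gram/kernel blocks.

    Built once per design matrix; arbitrary region subsets are then
    evaluated cheaply because a column subset's Gram is a slice of the
    cached full Gram (primal), or its kernel is assembled from per-region
    kernels (dual).
    """

    def __init__(self, design: WindowDataset, *, n_folds: int = 5,
                 n_candidates: int = 30, n_repeats: int = 10,
                 repeat_seeds: list[int] | None = None, base_seed: int = 0,
                 blocks_per_subject: int | None = None, mode: str = "auto"):
        self.design = design
        self.n_folds = n_folds
        self.n_candidates = n_candidates
        self.repeat_seeds = list(repeat_seeds) if repeat_seeds is not None \
            else list(range(n_repeats))
        self.base_seed = base_seed
        n, p = design.X.shape
        self.mode = mode  # auto: decided per region subset (primal iff p_sub <= n)
        self.subjects = design.subjects
        if len(self.subjects) < 2:
            raise InvalidDataError("LOSO needs at least 2 subjects")
        if blocks_per_subject is None:
            blocks_per_subject = max(
                2, int(np.ceil(2 * n_folds / max(len(self.subjects) - 1, 1))))
        # blocks are contiguous and subject-pure
        slices: list[slice] = []
        self.block_subject: list[str] = []
        groups = design.groups
        for subj in self.subjects:
            rows = np.flatnonzero(groups == subj)
            # a subject's windows may span several contiguous row ranges
            splits = np.flatnonzero(np.diff(rows) > 1) + 1
            ranges = np.split(rows, splits)
            target = max(len(rows) // blocks_per_subject, 1)
            for rr in ranges:
                lo, hi = rr[0], rr[-1] + 1
                k = max(1, round((hi - lo) / target))
                for sl in _contiguous_blocks(hi - lo, k):
                    slices.append(slice(lo + sl.start, lo + sl.stop))
                    self.block_subject.append(subj)
        self.block_subject = np.array(self.block_subject, dtype=object)
        self.slices = slices
        self._block_rows = [np.arange(sl.start, sl.stop) for sl in slices]
        self._train_rows = {
            subj: np.concatenate([rows for rows, s in
                                  zip(self._block_rows, self.block_subject)
                                  if s != subj])
            for subj in self.subjects}
        self._grams_cache: _PrimalGrams | None = None
        self._K_cache: np.ndarray | None = None
        self._region_kernels: dict[str, np.ndarray] = {}

    @property
    def _grams(self) -> _PrimalGrams:
        if self._grams_cache is None:
            self._grams_cache = _PrimalGrams(self.design.X, self.design.y,
                                             self.slices)
        return self._grams_cache

    @property
    def _K(self) -> np.ndarray:
        if self._K_cache is None:
            X = self.design.X
            self._K_cache = X @ X.T
        return self._K_cache

    def _mode_for(self, n_cols: int) -> str:
        if self.mode != "auto":
            return self.mode
        # primal normal equations when features fit; kernel form otherwise
        return "primal" if n_cols <= min(self.design.X.shape[0], 3000) else "dual"

    # -- helpers ---------------------------------------------------------
    def _cols(self, regions: list[str] | None) -> np.ndarray | None:
        if regions is None:
            return None
        if not regions:
            raise InvalidDataError("region subset must be nonempty")
        return self.design.columns_for(regions)

    def _kernel_for(self, regions: list[str] | None) -> np.ndarray:
        if regions is None or set(regions) == set(self.design.region_subset):
            return self._K
        if len(regions) > 16:  # direct product beats caching 84 n x n kernels
            Xs = self.design.X[:, self.design.columns_for(regions)]
            return Xs @ Xs.T
        K = None
        for r in regions:
            if r not in self._region_kernels:
                cols = self.design.region_columns(r)
                Xr = self.design.X[:, cols]
                self._region_kernels[r] = Xr @ Xr.T
            K = self._region_kernels[r] if K is None else K + self._region_kernels[r]
        return K

    # -- dual path -------------------------------------------------------
    def _dual_fit_predict(self, K, y, train_idx, test_idx, lam,
                          single_precision=False):
        Ktr = K[np.ix_(train_idx, train_idx)]
        v = Ktr.mean(axis=1)
        mu2 = float(v.mean())
        Kc = Ktr - v[:, None] - v[None, :] + mu2
        ntr = len(train_idx)
        Kc.flat[:: ntr + 1] += lam
        ym = y[train_idx].mean()
        rhs = y[train_idx] - ym
        if single_precision:
            # CV scoring only: candidate ranking tolerates fp32 rounding
            try:
                alpha = np.linalg.solve(Kc.astype(np.float32),
                                        rhs.astype(np.float32)).astype(float)
            except np.linalg.LinAlgError:
                alpha = _posv(Kc, rhs)
        else:
            alpha = _posv(Kc, rhs)
        Kxt = K[np.ix_(test_idx, train_idx)]
        vt = Kxt.mean(axis=1)
        pred = (Kxt - vt[:, None] - v[None, :] + mu2) @ alpha + ym
        return alpha, pred

    def _dual_optimize(self, K, y, train_blocks, lams, rng):
        best = (np.inf, lams[0])
        for lam in lams:
            folds = _partition_blocks(len(train_blocks), self.n_folds, rng)
            sse = 0.0
            nval = 0
            for fold in folds:
                val_rows = np.concatenate(
                    [self._block_rows[b] for b in train_blocks[fold]])
                tr_rows = np.concatenate(
                    [self._block_rows[b] for b in np.delete(train_blocks, fold)])
                _, pred = self._dual_fit_predict(K, y, tr_rows, val_rows, lam,
                                                 single_precision=True)
                resid = y[val_rows] - pred
                sse += float(resid @ resid)
                nval += len(val_rows)
            score = sse / nval
            if score < best[0]:
                best = (score, lam)
        return float(best[1])

    # -- public API ------------------------------------------------------
    def _prepare_subset(self, regions: list[str] | None):
        """Cache work shared by every LOSO fold of one region subset."""
        cols = self._cols(regions)
        n_cols = self.design.X.shape[1] if cols is None else len(cols)
        mode = self._mode_for(n_cols)
        if mode == "primal":
            p_full = self.design.X.shape[1]
            if cols is None:
                grams, Xv = self._grams, self.design.X
            elif p_full <= 2048 or self._grams_cache is not None:
                grams = self._grams.subset(cols)
                Xv = self.design.X[:, cols]
            else:
                # full-p Gram blocks would be huge; build subset Grams directly
                Xv = self.design.X[:, cols]
                grams = _PrimalGrams(Xv, self.design.y, self.slices)
            return mode, cols, grams, Xv
        return mode, cols, self._kernel_for(regions), None

    def evaluate_subject(self, held_out: str, regions: list[str] | None = None,
                         condition: str = "", return_models: bool = False,
                         fixed_lambdas: list[float] | None = None,
                         _prepared=None) -> FoldResult:
        design = self.design
        y = design.y
        all_blocks = np.arange(len(self.slices))
        train_blocks = all_blocks[self.block_subject != held_out]
        test_rows = np.flatnonzero(design.groups == held_out)
        if len(test_rows) < 2:
            raise InvalidDataError(f"held-out subject {held_out} has < 2 windows")
        n_train = int(sum(self.slices[b].stop - self.slices[b].start
                          for b in train_blocks))
        lams = lambda_grid(n_train, self.n_candidates)
        if _prepared is None:
            _prepared = self._prepare_subset(regions)
        mode = _prepared[0]
        if mode == "primal":
            _, cols, grams, Xv = _prepared
        else:
            _, cols, K, _ = _prepared
        rs, chosen, models = [], [], []
        for rep, seed in enumerate(self.repeat_seeds):
            rng = np.random.default_rng([seed, self.base_seed,
                                         self.subjects.index(held_out)])
            fixed = None if fixed_lambdas is None \
                else fixed_lambdas[min(rep, len(fixed_lambdas) - 1)]
            if mode == "primal":
                lam = fixed if fixed is not None else _grid_search_primal(
                    grams, Xv, y, train_blocks, lams, self.n_folds, rng)
                G = grams.G[train_blocks].sum(axis=0)
                c = grams.c[train_blocks].sum(axis=0)
                s = grams.s[train_blocks].sum(axis=0)
                ysum = grams.ysum[train_blocks].sum()
                beta, b0 = _solve_centered(G, c, s, ysum, n_train, lam)
                pred = Xv[test_rows] @ beta + b0
            else:
                lam = fixed if fixed is not None \
                    else self._dual_optimize(K, y, train_blocks, lams, rng)
                tr_rows = self._train_rows[held_out]
                alpha, pred = self._dual_fit_predict(K, y, tr_rows, test_rows, lam)
                if return_models:
                    Xtr = design.X[tr_rows] if cols is None \
                        else design.X[np.ix_(tr_rows, cols)]
                    beta = Xtr.T @ alpha - Xtr.mean(axis=0) * float(alpha.sum())
                    b0 = float(y[tr_rows].mean())
            rs.append(_pearson(pred, y[test_rows]))
            chosen.append(lam)
            if return_models:
                subset = regions if regions is not None else design.region_subset
                models.append(LinearModel(beta, b0, lam, list(subset),
                                          design.window_len))
        return FoldResult(held_out=held_out, r_per_seed=rs, lambdas=chosen,
                          condition=condition, models=models)

    def loso(self, regions: list[str] | None = None, condition: str = "",
             return_models: bool = False) -> list[FoldResult]:
        if len(self.subjects) < 3:
            raise InvalidDataError("LOSO evaluation needs >= 3 subjects")
        prepared = self._prepare_subset(regions)
        out = []
        for subj in self.subjects:
            try:
                out.append(self.evaluate_subject(subj, regions, condition,
                                                 return_models,
                                                 _prepared=prepared))
            except InvalidDataError as exc:
                warnings.warn(f"skipping subject {subj}: {exc}")
        return out


def evaluate_fold(design: WindowDataset, held_out: str,
                  regions: list[str] | None = None, n_repeats: int = 10,
                  **kwargs) -> FoldResult:
    """One LOSO fold: optimize lambda on training subjects, fit, test."""
    ev = LosoEvaluator(design, n_repeats=n_repeats, **kwargs)
    return ev.evaluate_subject(held_out, regions)


def loso_evaluate(design: WindowDataset, regions: list[str] | None = None,
                  n_repeats: int = 10, condition: str = "", **kwargs
                  ) -> list[FoldResult]:
    """Full leave-one-subject-out evaluation (one FoldResult per subject)."""
    ev = LosoEvaluator(design, n_repeats=n_repeats, **kwargs)
    return ev.loso(regions, condition)


# ---------------------------------------------------------------------------
# temporal-shuffle control

def shuffle_control(prepared: PreparedDataset, rng: np.random.Generator,
                    per_region: bool = False) -> PreparedDataset:
    """Destroy the EEG-fMRI temporal relation while keeping both marginals.

    Within each run, the TR order of the (cleaned, retained) fMRI matrix is
    randomly permuted — jointly across regions by default, preserving the
    spatial covariance — while the EEG targets keep their original
    temporal structure. Windowing afterwards yields the null condition.
    """
    by_run: dict[tuple[str, str], list[Segment]] = {}
    for seg in prepared.segments:
        by_run.setdefault((seg.subject_id, seg.run_id), []).append(seg)
    new_segments: dict[tuple[str, str, int], Segment] = {}
    for key, segs in by_run.items():
        stacked = np.vstack([s.fmri for s in segs])
        if per_region:
            shuffled = np.empty_like(stacked)
            for j in range(stacked.shape[1]):
                shuffled[:, j] = stacked[rng.permutation(len(stacked)), j]
        else:
            shuffled = stacked[rng.permutation(len(stacked))]
        pos = 0
        for s in segs:
            block = shuffled[pos: pos + s.n_tr]
            pos += s.n_tr
            new_segments[(s.subject_id, s.run_id, s.start)] = Segment(
                s.subject_id, s.run_id, s.start, block, dict(s.targets))
    segments = [new_segments[(s.subject_id, s.run_id, s.start)]
                for s in prepared.segments]
    return PreparedDataset(
        segments=segments, atlas=prepared.atlas,
        region_labels=list(prepared.region_labels),
        tr_seconds=prepared.tr_seconds, has_alpha=dict(prepared.has_alpha),
        dataset_id=prepared.dataset_id)


def null_loso(prepared: PreparedDataset, band: str, n_shuffles: int,
              rng: np.random.Generator, regions: list[str] | None = None,
              **evaluator_kwargs) -> np.ndarray:
    """Per-subject null r, averaged over independent temporal shuffles.

    Because overlapping windows make predictions strongly autocorrelated,
    a single shuffle's r has substantial spread; averaging over
    ``n_shuffles`` independent shuffles estimates the null mean with
    sd shrunk by sqrt(n_shuffles).
    """
    from .windows import assemble_design
    acc = None
    for _ in range(n_shuffles):
        shuffled = shuffle_control(prepared, rng)
        design = assemble_design(shuffled, None, band)
        ev = LosoEvaluator(design, **evaluator_kwargs)
        rvals = np.array([f.mean_r for f in ev.loso(regions, condition="control")])
        acc = rvals if acc is None else acc + rvals
    return acc / n_shuffles
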