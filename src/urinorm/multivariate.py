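"""Unit-variance PCA with NIPALS and cross-validated Q2.

The strategy comparison rests on unsupervised PCA of the autoscaled
(sample x metabolite) matrix.  Components are extracted one at a time
with NIPALS (nonlinear iterative partial least squares), which regresses
scores and loadings over *present* matrix elements only and therefore
tolerates missing values natively - the behaviour of the SIMCA family of
tools.  Model quality is summarised by R2X (fraction of total scaled
variance explained) and Q2 (cross-validated predictive ability,
1 - PRESS/SS); a small gap between the two indicates a model that fits
without over-fitting, which is the criterion used to rank normalisation
strategies.

Cross-validation deletes matrix *elements* (not whole samples) in
diagonal stripes: element (i, j) belongs to fold ``(i + j) mod k`` with
the fold labels shuffled by the seed.  Row-wise deletion is unstable on
30-sample unit-variance data; element-wise deletion keeps every row and
column represented in each training split.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CreatinineAssay, PeakTable, SampleSheet, UrinormError
from .normalise import NormalisedTable, apply_strategy


class MultivariateError(UrinormError):
    pass


@dataclasses.dataclass
class ScaledMatrix:
    """A samples x variables matrix after per-column centring and unit-
    variance scaling (SD with n-1 degrees of freedom).  Zero-variance or
    nearly-empty columns are dropped and recorded."""

    X: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def autoscale(data) -> ScaledMatrix:
    """Mean-centre and scale each variable to unit variance.

    ``data`` may be a :class:`PeakTable`/:class:`NormalisedTable`
    (metabolite x sample; transposed internally so samples become rows)
    or a samples x variables DataFrame.  Missing values stay missing.
    """
    if isinstance(data, (PeakTable, NormalisedTable)):
        frame = data.values.T
    elif isinstance(data, pd.DataFrame):
        frame = data
    else:
        raise MultivariateError("autoscale expects a peak table or a DataFrame")
    if frame.shape[0] < 2:
        raise MultivariateError("autoscaling needs at least 2 samples")
    X = frame.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X, axis=0)
        sds = np.nanstd(X, axis=0, ddof=1)
    n_present = np.isfinite(X).sum(axis=0)
    keep = (n_present >= 2) & np.isfinite(sds) & (sds > 0)
    dropped = [str(c) for c in frame.columns[~keep]]
    if not keep.any():
        raise MultivariateError("all variables have zero variance")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance/empty variables: "
                      f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}")
    Xs = (X[:, keep] - means[keep]) / sds[keep]
    return ScaledMatrix(
        X=Xs,
        sample_ids=[str(i) for i in frame.index],
        variable_ids=[str(c) for c in frame.columns[keep]],
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )


@dataclasses.dataclass
class PCAModel:
    """NIPALS PCA model: scores, unit-norm loadings, explained-variance
    bookkeeping and per-component convergence metadata."""

    scores: np.ndarray        # samples x components
    loadings: np.ndarray      # variables x components
    r2x_per_component: np.ndarray
    r2x_cumulative: np.ndarray
    total_ss: float
    residual_ss: np.ndarray   # residual SS after 0, 1, ..., A components
    n_iterations: list[int]
    converged: list[bool]
    sample_ids: list[str] | None = None
    variable_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        return self.scores[:, :a] @ self.loadings[:, :a].T


def _as_array(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, ScaledMatrix):
        return X.X, X.sample_ids, X.variable_ids
    return np.asarray(X, dtype=float), None, None


def _em_refine(Xa: np.ndarray, mask: np.ndarray, n_components: int,
               max_iter: int = 1000, rtol: float = 1e-10
               ) -> tuple[np.ndarray, np.ndarray]:
    """Missing-value PCA by expectation-maximisation: impute missing
    elements from the current rank-A reconstruction (starting from the
    column mean, i.e. zero after centring) and refit by SVD until the
    imputations stabilise.

    Per-component regressions over present elements only (sequential
    NIPALS deflation) are biased when elements are missing, and on
    unstructured data they can converge to degenerate loadings that
    concentrate on sparsely observed variables, with exploding scores;
    iterating imputation and a full-rank-A refit is the stable classical
    alternative and converges to the joint least-squares fit of the
    present elements.
    """
    Xc = np.where(mask, Xa, 0.0)
    scale = float(np.abs(Xc).max()) or 1.0
    for _ in range(max_iter):
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :n_components] * S[:n_components]) @ Vt[:n_components]
        delta = float(np.abs(recon[~mask] - Xc[~mask]).max(initial=0.0))
        Xc[~mask] = recon[~mask]
        if delta <= rtol * scale:
            break
    T = U[:, :n_components] * S[:n_components]
    P = Vt[:n_components].T
    for a in range(n_components):
        k = int(np.argmax(np.abs(P[:, a])))
        if P[k, a] < 0:
            P[:, a] = -P[:, a]
            T[:, a] = -T[:, a]
    return T, P


def nipals_pca(X, n_components: int, tol: float = 1e-9,
               max_iter: int = 500, refine_missing: bool = True) -> PCAModel:
    """Extract ``n_components`` principal components by NIPALS.

    Each component is initialised with the residual column of largest
    variance (ties broken by lowest index), then alternates loading and
    score regressions computed over present elements only, normalises the
    loading, and checks the relative change of the score vector against
    ``tol``.  After convergence the component is deflated from the
    residual.  R2X per component is the drop in residual sum of squares
    divided by the total sum of squares.

    When the matrix contains missing elements the model is refined by
    iterating imputation of the missing elements from the current
    reconstruction and a full refit (``refine_missing``); complete
    matrices take the plain NIPALS path unchanged.
    """
    Xa, sample_ids, variable_ids = _as_array(X)
    n, m = Xa.shape
    if n_components > min(n - 1, m):
        raise MultivariateError(
            f"n_components={n_components} exceeds min(n_samples - 1, n_variables)"
            f" = {min(n - 1, m)}"
        )
    mask = np.isfinite(Xa)
    if not mask.any():
        raise MultivariateError("matrix has no present elements")
    R = np.where(mask, Xa, 0.0)  # residual, zeros at missing positions
    fmask = mask.astype(float)
    ss0 = float((R ** 2).sum())
    if ss0 == 0:
        raise MultivariateError("matrix is identically zero")

    scores = np.zeros((n, n_components))
    loadings = np.zeros((m, n_components))
    r2x = np.zeros(n_components)
    residual_ss = [ss0]
    n_iterations: list[int] = []
    converged_flags: list[bool] = []
    ss_prev = ss0

    for a in range(n_components):
        # column variances of the residual over present elements
        with np.errstate(invalid="ignore", divide="ignore"):
            cnt = fmask.sum(axis=0)
            mu = R.sum(axis=0) / np.maximum(cnt, 1)
            var = ((R - mu[None, :] * fmask) ** 2).sum(axis=0) / np.maximum(cnt - 1, 1)
        var[cnt < 2] = -np.inf
        t = R[:, int(np.argmax(var))].copy()
        if not np.any(t):
            t = np.where(mask.any(axis=1), 1.0, 0.0)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            denom_p = (t ** 2) @ fmask
            with np.errstate(invalid="ignore", divide="ignore"):
                p = (t @ R) / denom_p
            p[denom_p == 0] = 0.0
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = fmask @ (p ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = (R @ p) / denom_t
            t_new[denom_t == 0] = 0.0
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(np.linalg.norm(t), 1e-300):
                converged = True
                break
        if not converged:
            warnings.warn(f"NIPALS component {a + 1} did not converge in {max_iter} iterations")
        # sign convention: largest-magnitude loading element positive
        k = int(np.argmax(np.abs(p)))
        if p[k] < 0:
            p = -p
            t = -t
        R = R - np.outer(t, p) * fmask
        ss_after = float((R ** 2).sum())
        scores[:, a] = t
        loadings[:, a] = p
        r2x[a] = (ss_prev - ss_after) / ss0
        residual_ss.append(ss_after)
        ss_prev = ss_after
        n_iterations.append(it)
        converged_flags.append(converged)

    if refine_missing and not mask.all() and n_components >= 1:
        Xf = np.where(mask, Xa, 0.0)
        scores, loadings = _em_refine(Xa, mask, n_components)
        residual_ss = [ss0]
        pred = np.zeros_like(Xf)
        for a in range(n_components):
            pred += np.outer(scores[:, a], loadings[:, a])
            residual_ss.append(float(((Xf - pred * fmask) ** 2).sum()))
        r2x = -np.diff(residual_ss) / ss0

    return PCAModel(
        scores=scores,
        loadings=loadings,
        r2x_per_component=r2x,
        r2x_cumulative=np.cumsum(r2x),
        total_ss=ss0,
        residual_ss=np.asarray(residual_ss),
        n_iterations=n_iterations,
        converged=converged_flags,
        sample_ids=sample_ids,
        variable_ids=variable_ids,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclasses.dataclass
class Q2Result:
    q2_per_component: np.ndarray
    q2_cumulative: np.ndarray
    press: np.ndarray          # PRESS after 1..A components (cumulative predictions)
    rss: np.ndarray            # full-model residual SS after 0..A components
    folds: np.ndarray          # fold label per matrix element (-1 where missing)


def _stripe_folds(mask: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    n, m = mask.shape
    stripe = (np.arange(n)[:, None] + np.arange(m)[None, :]) % n_folds
    perm = rng.permutation(n_folds)
    folds = perm[stripe]
    folds[~mask] = -1
    return folds


def _folds_valid(mask: np.ndarray, folds: np.ndarray, n_folds: int) -> bool:
    for f in range(n_folds):
        train = mask & (folds != f)
        if (~train.any(axis=1)).any() or (~train.any(axis=0)).any():
            return False
    return True


def cross_validated_q2(X, n_components: int, n_folds: int = 7,
                       seed: int = 0, tol: float = 1e-9,
                       max_iter: int = 500) -> Q2Result:
    """Element-wise k-fold cross-validated Q2.

    For each fold the assigned elements are hidden, a NIPALS model is
    fitted on the remainder and the hidden elements are predicted from
    the cumulative score x loading reconstruction.  With ``PRESS_a`` the
    total held-out squared error after ``a`` components and ``RSS_a`` the
    full-data residual sum of squares (``RSS_0`` = total SS):

    ``Q2_a = 1 - PRESS_a / RSS_{a-1}``
    ``Q2_cum(A) = 1 - prod_{a<=A} PRESS_a / RSS_{a-1}``
    """
    Xa, _, _ = _as_array(X)
    mask = np.isfinite(Xa)
    if n_folds < 2:
        raise MultivariateError("n_folds must be >= 2")
    if mask.sum() < n_folds * n_components:
        raise MultivariateError("too few present elements for the requested CV")
    rng = np.random.default_rng(seed)
    folds = _stripe_folds(mask, n_folds, rng)
    attempts = 0
    while not _folds_valid(mask, folds, n_folds):
        attempts += 1
        if attempts > 20:
            raise MultivariateError("could not build a valid CV fold assignment")
        warnings.warn("diagonal striping left a fold with an empty training row or "
                      "column; re-assigning folds at random")
        folds = np.where(mask, rng.integers(0, n_folds, size=mask.shape), -1)

    full = nipals_pca(Xa, n_components, tol=tol, max_iter=max_iter)
    rss = full.residual_ss  # length A+1, rss[0] = total SS

    press = np.zeros(n_components)
    for f in range(n_folds):
        held = mask & (folds == f)
        if not held.any():
            continue
        Xtrain = Xa.copy()
        Xtrain[held] = np.nan
        model = nipals_pca(Xtrain, n_components, tol=tol, max_iter=max_iter)
        pred = np.zeros_like(Xa)
        for a in range(n_components):
            pred += np.outer(model.scores[:, a], model.loadings[:, a])
            err = Xa[held] - pred[held]
            press[a] += float((err ** 2).sum())

    ratios = press / rss[:-1]
    q2_per = 1.0 - ratios
    q2_cum = 1.0 - np.cumprod(ratios)
    return Q2Result(q2_per_component=q2_per, q2_cumulative=q2_cum,
                    press=press, rss=rss, folds=folds)


# ---------------------------------------------------------------------------
# strategy comparison panel


@dataclasses.dataclass
class StrategyPanel:
    """Per-strategy PCA models with phase-annotated scores and the
    goodness-of-fit vs predicted-fit comparison report."""

    models: dict[str, PCAModel]
    q2: dict[str, Q2Result]
    normalised: dict[str, NormalisedTable]
    scores: pd.DataFrame
    report: pd.DataFrame


def fit_strategy_panel(peaks: PeakTable, sheet: SampleSheet,
                       strategies: Sequence[str] = ("area_percent", "ms_creatinine",
                                                    "pooled_ms_creatinine",
                                                    "assay_creatinine"),
                       assay: CreatinineAssay | None = None,
                       pooled: Mapping[str, float] | None = None,
                       creatinine_feature: str | None = None,
                       missing_policy: str = "as_zero",
                       n_components: int = 2, n_folds: int = 7,
                       seed: int = 0) -> StrategyPanel:
    """Fit one PCA per normalisation strategy and rank them by the gap
    |R2X_cum - Q2_cum| (smallest gap = best-behaved model).

    Samples are ordered by subject and collection index so every strategy
    sees the identical matrix layout and the identical CV fold pattern.
    """
    deduped = list(dict.fromkeys(strategies))
    if len(deduped) < len(list(strategies)):
        warnings.warn("duplicate strategies requested; deduplicated")
    sheet.check_covers(peaks)
    order = [s for s in sheet.ordered_samples() if s in peaks.values.columns]

    models: dict[str, PCAModel] = {}
    q2s: dict[str, Q2Result] = {}
    normalised: dict[str, NormalisedTable] = {}
    score_rows = []
    report_rows = []
    for strategy in deduped:
        table = apply_strategy(strategy, peaks, sheet, assay=assay, pooled=pooled,
                               creatinine_feature=creatinine_feature,
                               missing_policy=missing_policy)
        normalised[strategy] = table
        scaled = autoscale(table.values[order].T)
        model = nipals_pca(scaled, n_components)
        q2 = cross_validated_q2(scaled, n_components, n_folds=n_folds, seed=seed)
        models[strategy] = model
        q2s[strategy] = q2
        for i, sid in enumerate(order):
            row = {"strategy": strategy, "sample_id": sid,
                   "subject_id": sheet.frame.loc[sid, "subject_id"],
                   "timepoint_label": sheet.frame.loc[sid, "timepoint_label"],
                   "phase": sheet.frame.loc[sid, "phase"]}
            for a in range(n_components):
                row[f"t{a + 1}"] = model.scores[i, a]
            score_rows.append(row)
        r2x_cum = float(model.r2x_cumulative[-1])
        q2_cum = float(q2.q2_cumulative[-1])
        report_rows.append({
            "strategy": strategy,
            "r2x_cumulative": r2x_cum,
            "q2_cumulative": q2_cum,
            "gap": abs(r2x_cum - q2_cum),
        })
    report = pd.DataFrame(report_rows).sort_values("gap", kind="mergesort").reset_index(drop=True)
    return StrategyPanel(models=models, q2=q2s, normalised=normalised,
                         scores=pd.DataFrame(score_rows), report=report)


def plot_scores(panel: StrategyPanel, out_dir, colour_by: str = "phase"):
    """One score plot PNG per strategy, coloured by phase (or subject)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for strategy in panel.models:
        sub = panel.scores[panel.scores["strategy"] == strategy]
        fig, ax = plt.subplots(figsize=(5, 4))
        for value, grp in sub.groupby(colour_by):
            ax.scatter(grp["t1"], grp["t2"], label=str(value), alpha=0.8)
        ax.set_xlabel("t[1]")
        ax.set_ylabel("t[2]")
        ax.set_title(strategy)
        ax.legend(fontsize="small")
        fig.tight_layout()
        target = out_dir / f"scores_{strategy}.png"
        fig.savefig(target, dpi=120)
        plt.close(fig)
        written.append(target)
    return written
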