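"""Latent-variable models and their validation diagnostics.

PCA (mean-centred) gives the unsupervised overview; PLS-DA (Pareto-scaled,
NIPALS) the supervised one; pairwise OPLS-DA concentrates the between-class
difference into a single predictive component after removing
response-orthogonal variation.  Model quality is reported as R2X/R2Y
(explained variance) and Q2 (1 - PRESS/SS over stratified 10-fold
cross-validation, SIMCA-style pooled PRESS); validity via a response
permutation test and CV-ANOVA.

Conventions adopted here and used downstream:

* Pareto scaling divides each centred column by the square root of its
  sample (n-1) standard deviation; constant columns are left unscaled and
  flagged.
* Two-class responses are coded -1 (first class by order of appearance) /
  +1 (second class) and centred; the OPLS-DA predictive score is sign-fixed
  so that it correlates positively with the +1 class.
* CV-ANOVA follows the Eriksson formulation: F = ((SS - PRESS)/d1) /
  (PRESS/d2) with d1 = number of fitted latent components (predictive plus
  orthogonal) and d2 = N - 1 - d1, compared against the F(d1, d2)
  distribution.  PRESS >= SS clamps F to 0 (p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScalingSpec",
    "LatentModel",
    "ModelSpec",
    "CvResult",
    "PermutationResult",
    "CvAnovaResult",
    "scale_matrix",
    "fit_pca",
    "fit_plsda",
    "fit_oplsda",
    "fit_model",
    "cross_validated_q2",
    "permutation_test",
    "cv_anova",
    "encode_two_class",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# scaling

@dataclass(frozen=True)
class ScalingSpec:
    """Column centring/scaling parameters, reusable on new data."""

    mode: str                      # "mean_center" | "pareto"
    means: np.ndarray
    scale: np.ndarray              # 1 for mean_center; sqrt(sd) for pareto
    constant_columns: np.ndarray   # boolean flags

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means) / self.scale

    def invert(self, xs: np.ndarray) -> np.ndarray:
        return np.asarray(xs, dtype=float) * self.scale + self.means


def scale_matrix(
    values: np.ndarray, mode: str = "mean_center"
) -> tuple[np.ndarray, ScalingSpec]:
    """Mean-centre, or Pareto-scale (centred / sqrt(sample sd)), a matrix."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if mode not in ("mean_center", "pareto"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    means = x.mean(axis=0)
    if mode == "mean_center":
        scale = np.ones(x.shape[1])
        constant = x.std(axis=0) == 0.0
    else:
        sd = x.std(axis=0, ddof=1)
        constant = sd <= _EPS
        scale = np.where(constant, 1.0, np.sqrt(np.where(constant, 1.0, sd)))
    spec = ScalingSpec(mode=mode, means=means, scale=scale,
                       constant_columns=constant)
    return spec.apply(x), spec


# ---------------------------------------------------------------------------
# models

@dataclass
class LatentModel:
    """A fitted PCA / PLS-DA / OPLS-DA decomposition."""

    kind: str
    scores: np.ndarray                       # samples x predictive components
    loadings: np.ndarray                     # variables x predictive components
    r2x: float
    r2x_per_component: np.ndarray
    weights: np.ndarray | None = None        # variables x components (pls/opls)
    y_loadings: np.ndarray | None = None
    r2y: float | None = None
    classes: tuple[str, ...] | None = None
    y: np.ndarray | None = None              # centred response used in the fit
    y_mean: float | np.ndarray | None = None
    scores_orth: np.ndarray | None = None
    loadings_orth: np.ndarray | None = None
    weights_orth: np.ndarray | None = None
    scaling: ScalingSpec | None = None

    @property
    def n_predictive(self) -> int:
        return self.scores.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return 0 if self.scores_orth is None else self.scores_orth.shape[1]

    @property
    def n_components(self) -> int:
        return self.n_predictive + self.n_orthogonal

    def filter_orthogonal(self, xs: np.ndarray) -> np.ndarray:
        """Remove the fitted y-orthogonal components from (scaled) new data."""
        xr = np.array(xs, dtype=float, copy=True)
        if self.weights_orth is not None:
            for a in range(self.weights_orth.shape[1]):
                w_o = self.weights_orth[:, a]
                p_o = self.loadings_orth[:, a]
                t_o = xr @ w_o
                xr -= np.outer(t_o, p_o)
        return xr

    def predict_scores(self, xs: np.ndarray) -> np.ndarray:
        if self.kind == "pca":
            return np.asarray(xs) @ self.loadings
        xr = self.filter_orthogonal(xs)
        if self.kind == "oplsda":
            return (xr @ self.weights[:, :1])
        # PLS with deflation: use the R = W (P'W)^-1 rotation
        w, p = self.weights, self.loadings
        rot = w @ np.linalg.pinv(p.T @ w)
        return xr @ rot

    def predict_response(self, xs: np.ndarray) -> np.ndarray:
        """Predicted (uncentred) response for scaled new data."""
        if self.kind == "pca":
            raise ValueError("PCA has no response to predict")
        t = self.predict_scores(xs)
        yhat = t @ np.atleast_2d(self.y_loadings).reshape(t.shape[1], -1)
        out = yhat + self.y_mean
        return out[:, 0] if out.shape[1] == 1 else out


def fit_pca(xs: np.ndarray, n_components: int = 2,
            scaling: ScalingSpec | None = None) -> LatentModel:
    """PCA of an already-scaled matrix via SVD.

    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    x = np.asarray(xs, dtype=float)
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for shape {x.shape}"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    total = float((x * x).sum())
    per_comp = (s[:n_components] ** 2) / max(total, _EPS)
    return LatentModel(
        kind="pca", scores=scores, loadings=loadings,
        r2x=float(per_comp.sum()), r2x_per_component=per_comp,
        scaling=scaling,
    )


def _unique_in_order(labels: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in labels:
        seen.setdefault(g, None)
    return tuple(seen)


def encode_two_class(groups: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    """-1/+1 coding; the first class by order of appearance gets -1."""
    classes = _unique_in_order(groups)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    y = np.where(np.asarray(groups) == classes[1], 1.0, -1.0)
    return y, (classes[0], classes[1])


def _encode_response(groups: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = _unique_in_order(groups)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    g = np.asarray(groups)
    for c in classes:
        if (g == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if len(classes) == 2:
        y, _ = encode_two_class(groups)
        return y[:, None], classes
    y = np.stack([(g == c).astype(float) for c in classes], axis=1)
    return y, classes


def fit_plsda(
    xs: np.ndarray,
    groups: Sequence[str],
    n_components: int = 2,
    scaling: ScalingSpec | None = None,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> LatentModel:
    """NIPALS PLS-DA on an already-scaled matrix.

    Two classes use a single centred -1/+1 response column; more classes use
    centred one-hot columns (PLS2).  Predictors are deflated per component.
    """
    x = np.array(xs, dtype=float, copy=True)
    y_raw, classes = _encode_response(groups)
    y_mean = y_raw.mean(axis=0)
    y = y_raw - y_mean
    n, p = x.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("invalid number of components")
    x0ss = float((x * x).sum())
    y0ss = float((y * y).sum())
    ws, ts, ps, qs, r2x_comp = [], [], [], [], []
    for _ in range(n_components):
        u = y[:, int(np.argmax(y.var(axis=0)))].copy()
        if float(u @ u) <= _EPS:
            break
        w = np.zeros(p)
        for _ in range(max_iter):
            w = x.T @ u / max(float(u @ u), _EPS)
            w /= max(float(np.linalg.norm(w)), _EPS)
            t = x @ w
            q = y.T @ t / max(float(t @ t), _EPS)
            u_new = y @ q / max(float(q @ q), _EPS)
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), _EPS):
                u = u_new
                break
            u = u_new
        t = x @ w
        pv = x.T @ t / max(float(t @ t), _EPS)
        q = y.T @ t / max(float(t @ t), _EPS)
        x -= np.outer(t, pv)
        y = y - np.outer(t, q)
        ws.append(w); ts.append(t); ps.append(pv); qs.append(q)
        r2x_comp.append(float(t @ t) * float(pv @ pv) / max(x0ss, _EPS))
    scores = np.stack(ts, axis=1)
    return LatentModel(
        kind="plsda",
        scores=scores,
        loadings=np.stack(ps, axis=1),
        weights=np.stack(ws, axis=1),
        y_loadings=np.stack(qs, axis=0),  # components x response columns
        r2x=float(np.sum(r2x_comp)),
        r2x_per_component=np.asarray(r2x_comp),
        r2y=1.0 - float((y * y).sum()) / max(y0ss, _EPS),
        classes=classes,
        y=y_raw - y_mean,
        y_mean=y_mean if y_mean.size > 1 else float(y_mean[0]),
        scaling=scaling,
    )


def fit_oplsda(
    xs: np.ndarray,
    groups: Sequence[str],
    n_orth: int = 1,
    scaling: ScalingSpec | None = None,
) -> LatentModel:
    """Two-class OPLS-DA: n_orth orthogonal components, one predictive.

    The orthogonal filter follows the standard OSC construction: the
    candidate orthogonal weight is the part of each component's loading that
    is orthogonal to the predictive weight w ~ X'y, so every orthogonal
    score has exactly zero sample correlation with the response.  With
    ``n_orth=0`` this reduces to single-component PLS.
    """
    classes = _unique_in_order(groups)
    if len(classes) != 2:
        raise ValueError(
            f"OPLS-DA is pairwise; got classes {classes}. "
            "Run each pair separately."
        )
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    x = np.array(xs, dtype=float, copy=True)
    y_signed, _ = encode_two_class(groups)
    y_mean = float(y_signed.mean())
    y = y_signed - y_mean
    x0ss = float((x * x).sum())
    yss = float(y @ y)

    w = x.T @ y
    w /= max(float(np.linalg.norm(w)), _EPS)
    w_os, t_os, p_os = [], [], []
    for _ in range(n_orth):
        t = x @ w
        pv = x.T @ t / max(float(t @ t), _EPS)
        w_o = pv - float(w @ pv) * w
        n_wo = float(np.linalg.norm(w_o))
        if n_wo <= 1e-10:   # no y-orthogonal structure left
            break
        w_o /= n_wo
        t_o = x @ w_o
        p_o = x.T @ t_o / max(float(t_o @ t_o), _EPS)
        x -= np.outer(t_o, p_o)
        w_os.append(w_o); t_os.append(t_o); p_os.append(p_o)

    t = x @ w
    pv = x.T @ t / max(float(t @ t), _EPS)
    q = float(y @ t) / max(float(t @ t), _EPS)
    if q < 0:   # sign-fix: predictive score correlates positively with +1 class
        w, t, pv, q = -w, -t, -pv, -q
    r2y = 1.0 - float(((y - t * q) ** 2).sum()) / max(yss, _EPS)
    r2x_pred = float(t @ t) * float(pv @ pv) / max(x0ss, _EPS)
    r2x_orth = [
        float(t_o @ t_o) * float(p_o @ p_o) / max(x0ss, _EPS)
        for t_o, p_o in zip(t_os, p_os)
    ]
    return LatentModel(
        kind="oplsda",
        scores=t[:, None],
        loadings=pv[:, None],
        weights=w[:, None],
        y_loadings=np.array([[q]]),
        r2x=r2x_pred + float(np.sum(r2x_orth)),
        r2x_per_component=np.asarray([r2x_pred] + r2x_orth),
        r2y=r2y,
        classes=classes,
        y=y,
        y_mean=y_mean,
        scores_orth=np.stack(t_os, axis=1) if t_os else None,
        loadings_orth=np.stack(p_os, axis=1) if p_os else None,
        weights_orth=np.stack(w_os, axis=1) if w_os else None,
        scaling=scaling,
    )


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ModelSpec:
    """How to build the supervised model inside CV/permutation loops."""

    kind: str = "oplsda"           # "oplsda" | "plsda"
    n_components: int = 1          # predictive components (plsda)
    n_orth: int = 1                # orthogonal components (oplsda)
    scaling: str = "pareto"

    def fit(self, xs: np.ndarray, groups: Sequence[str],
            scaling: ScalingSpec | None = None) -> LatentModel:
        if self.kind == "oplsda":
            return fit_oplsda(xs, groups, n_orth=self.n_orth, scaling=scaling)
        if self.kind == "plsda":
            return fit_plsda(xs, groups, n_components=self.n_components,
                             scaling=scaling)
        raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def n_total_components(self) -> int:
        return (1 + self.n_orth) if self.kind == "oplsda" else self.n_components


def fit_model(values: np.ndarray, groups: Sequence[str],
              spec: ModelSpec) -> LatentModel:
    """Scale raw values per the spec, then fit."""
    xs, scaling = scale_matrix(values, spec.scaling)
    return spec.fit(xs, groups, scaling=scaling)


@dataclass
class CvResult:
    q2: float
    press: float
    ss: float
    predictions: np.ndarray   # uncentred predicted response per sample
    y: np.ndarray             # -1/+1 (or one-hot) coded response
    folds: np.ndarray         # fold index per sample
    n_samples: int
    spec: ModelSpec

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.predictions


def cross_validated_q2(
    values: np.ndarray,
    groups: Sequence[str],
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Q2 = 1 - PRESS/SS over stratified k-fold CV, no leakage.

    Scaling parameters are re-estimated inside every training fold and
    applied to the held-out samples; PRESS is pooled over folds against the
    globally centred response sum of squares (SIMCA convention).  Fold
    assignment is stratified by class and deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    y_full, _ = _encode_response(g)
    if y_full.shape[1] == 1:
        y_full = y_full[:, 0]
    counts = pd.Series(g).value_counts()
    if k > int(counts.min()):
        raise ValueError(
            f"k={k} exceeds the smallest class size ({int(counts.min())})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    predictions = np.zeros_like(y_full, dtype=float)
    folds = np.full(len(g), -1, dtype=int)
    for fold, (train, test) in enumerate(skf.split(x, g)):
        assert len(set(g[train])) == len(set(g)), "fold lost a class"
        xs_train, scaling = scale_matrix(x[train], spec.scaling)
        model = spec.fit(xs_train, g[train], scaling=scaling)
        xs_test = scaling.apply(x[test])
        predictions[test] = model.predict_response(xs_test)
        folds[test] = fold
    y_centered = y_full - y_full.mean(axis=0)
    press = float(((y_full - predictions) ** 2).sum())
    ss = float((y_centered ** 2).sum())
    return CvResult(
        q2=1.0 - press / max(ss, _EPS), press=press, ss=ss,
        predictions=predictions, y=y_full, folds=folds,
        n_samples=len(g), spec=spec,
    )


@dataclass
class PermutationResult:
    n_permutations: int
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    label_correlations: np.ndarray
    observed_r2y: float
    observed_q2: float
    p_q2: float
    r2_intercept: float
    q2_intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label_correlation": self.label_correlations,
            "r2y": self.permuted_r2y,
            "q2": self.permuted_q2,
        })


def permutation_test(
    values: np.ndarray,
    groups: Sequence[str],
    spec: ModelSpec = ModelSpec(),
    n: int = 200,
    k: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Response permutation test: refit under shuffled class labels.

    R2Y and (cross-validated) Q2 are recomputed for each of ``n`` label
    permutations.  The empirical p-value is
    ``(1 + #{perm Q2 >= observed Q2}) / (n + 1)``.  The reported intercepts
    are the least-squares values of R2Y and Q2 at zero label correlation,
    fitted over the permuted points plus the observed point at correlation 1
    (the SIMCA-style validation plot).
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(groups)
    y_obs, _ = _encode_response(g)
    xs, _ = scale_matrix(values, spec.scaling)
    observed_r2y = float(spec.fit(xs, g).r2y)
    observed_q2 = cross_validated_q2(
        values, g, spec, k=k, seed=int(rng.integers(2 ** 31))
    ).q2

    perm_r2y = np.empty(n)
    perm_q2 = np.empty(n)
    corrs = np.empty(n)
    for i in range(n):
        perm = rng.permutation(len(g))
        gp = g[perm]
        y_perm = y_obs[perm]
        corrs[i] = _label_correlation(y_perm, y_obs)
        perm_r2y[i] = float(spec.fit(xs, gp).r2y)
        perm_q2[i] = cross_validated_q2(
            values, gp, spec, k=k, seed=int(rng.integers(2 ** 31))
        ).q2
    p_q2 = (1.0 + float((perm_q2 >= observed_q2).sum())) / (n + 1.0)
    cx = np.concatenate([corrs, [1.0]])
    r2_line = np.polyfit(cx, np.concatenate([perm_r2y, [observed_r2y]]), 1)
    q2_line = np.polyfit(cx, np.concatenate([perm_q2, [observed_q2]]), 1)
    return PermutationResult(
        n_permutations=n,
        permuted_r2y=perm_r2y,
        permuted_q2=perm_q2,
        label_correlations=corrs,
        observed_r2y=observed_r2y,
        observed_q2=observed_q2,
        p_q2=p_q2,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
    )


def _label_correlation(y_perm: np.ndarray, y_obs: np.ndarray) -> float:
    a = np.asarray(y_perm, dtype=float).reshape(len(y_perm), -1)
    b = np.asarray(y_obs, dtype=float).reshape(len(y_obs), -1)
    vals = []
    for j in range(a.shape[1]):
        sa, sb = a[:, j].std(), b[:, j].std()
        if sa <= _EPS or sb <= _EPS:
            continue
        vals.append(abs(float(np.corrcoef(a[:, j], b[:, j])[0, 1])))
    return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class CvAnovaResult:
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float


def cv_anova(cv: CvResult, n_model_df: int | None = None) -> CvAnovaResult:
    """F-test of cross-validated residuals against total response variation.

    ``d1`` = number of latent components fitted (predictive + orthogonal),
    ``d2`` = N - 1 - d1.  F = ((SS - PRESS)/d1) / (PRESS/d2); PRESS >= SS is
    clamped to F = 0, p = 1.
    """
    d1 = n_model_df if n_model_df is not None else cv.spec.n_total_components
    d2 = cv.n_samples - 1 - d1
    if d1 < 1 or d2 < 1:
        raise ValueError("not enough samples for the requested model df")
    if cv.press >= cv.ss:
        return CvAnovaResult(0.0, d1, d2, 1.0)
    f = ((cv.ss - cv.press) / d1) / (cv.press / d2)
    return CvAnovaResult(
        f_statistic=float(f), df_model=d1, df_residual=d2,
        p_value=float(stats.f.sf(f, d1, d2)),
    )
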