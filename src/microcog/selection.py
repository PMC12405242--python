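"""Discriminant feature selection.

Four routes into the discriminant feature sets used by the balance indices:

* :class:`LefseSelector` — Kruskal-Wallis screen followed by a bootstrapped
  linear-discriminant effect size on a 1e6 abundance scale (LDA score,
  log10), for taxa.
* :func:`pathway_screen` — mean-abundance gate plus exact rank-sum test,
  for functional pathways.
* :class:`SparsePLSDA` — cardinality-constrained PLS-DA (keepX non-zero
  loading weights per component) for metabolite shortlisting, followed by
  :func:`splsda_wilcoxon_filter`.
* :class:`Pc1Selector` — signed PC1-loading thresholds on the discriminant
  metabolites, producing the up/down sets of the metabolome index.

All estimators follow the scikit-learn fit/transform protocol and are
deterministic given ``random_state``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .stats import kruskal_wallis, exact_rank_sum

logger = logging.getLogger(__name__)

LEFSE_SCALE = 1e6  # per-sample abundance rescaling used by the LDA effect size


@dataclass
class DiscriminantSet:
    """Features flagged enriched in one of the two groups.

    ``frame`` is indexed by feature id with columns ``direction`` (group
    label the feature is enriched in), ``p_value``, ``score`` (LDA score for
    taxa, |loading weight| for metabolites, NaN when not applicable) and
    ``stage`` (selection provenance).
    """

    frame: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        req = {"direction", "p_value", "score", "stage"}
        if not req <= set(self.frame.columns):
            raise ValueError(f"DiscriminantSet frame needs columns {sorted(req)}")
        if len(self.frame) and (self.frame["p_value"] >= self.alpha).any():
            raise ValueError("retained features must have p < alpha")

    def features(self, direction: str | None = None) -> list[str]:
        if direction is None:
            return list(self.frame.index)
        return list(self.frame.index[self.frame["direction"] == direction])

    def __len__(self) -> int:
        return len(self.frame)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def _two_classes(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {list(classes)}")
    return y, classes


def _direction(values: np.ndarray, mask_a: np.ndarray, a: str, b: str) -> str:
    med_a = np.median(values[mask_a])
    med_b = np.median(values[~mask_a])
    return a if med_a > med_b else b


class LefseSelector(BaseEstimator):
    """LDA-effect-size discriminant taxon selection.

    A Kruskal-Wallis test screens features at ``alpha``; surviving candidates
    are scored by repeated balanced subsampling (fraction ``subsample`` per
    class, ``n_boot`` rounds) with a one-dimensional LDA fitted on the
    candidate block. The per-feature effect size averages the raw class-mean
    difference with the feature's share of the class separation along the
    discriminant axis, on abundances rescaled to sum 1e6 per sample; the LDA
    score is its log10 and features are retained when it exceeds
    ``lda_threshold``.
    """

    def __init__(self, alpha: float = 0.05, lda_threshold: float = 2.0,
                 n_boot: int = 30, subsample: float = 2.0 / 3.0,
                 random_state: int | None = None):
        self.alpha = alpha
        self.lda_threshold = lda_threshold
        self.n_boot = n_boot
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        frame = _as_frame(X)
        y, classes = _two_classes(y)
        rng = np.random.default_rng(self.random_state)
        vals = frame.to_numpy(dtype=float)
        # per-sample rescaling to the 1e6 scale used for the effect size
        row_sums = vals.sum(axis=1, keepdims=True)
        if (row_sums <= 0).any():
            raise ValueError("samples with zero total abundance")
        scaled = vals / row_sums * LEFSE_SCALE
        mask_a = y == classes[0]

        pvals = np.full(frame.shape[1], np.nan)
        skipped = []
        for j in range(frame.shape[1]):
            col = vals[:, j]
            if np.all(col == col[0]):
                skipped.append(str(frame.columns[j]))
                continue
            _, pvals[j] = kruskal_wallis([col[mask_a], col[~mask_a]])
        if skipped:
            warnings.warn(
                f"{len(skipped)} zero-variance feature(s) skipped "
                f"(e.g. {skipped[0]!r})",
                stacklevel=2,
            )

        cand = np.flatnonzero(pvals < self.alpha)
        scores = np.full(frame.shape[1], np.nan)
        if cand.size:
            scores[cand] = self._lda_scores(scaled[:, cand], mask_a, rng)

        self.feature_names_in_ = np.asarray(frame.columns)
        self.classes_ = classes
        self.pvalues_ = pvals
        self.scores_ = scores
        self.support_ = (scores > self.lda_threshold) & (pvals < self.alpha)
        self.directions_ = np.array([
            _direction(vals[:, j], mask_a, str(classes[0]), str(classes[1]))
            if self.support_[j] else ""
            for j in range(frame.shape[1])
        ], dtype=object)
        return self

    def _lda_scores(self, block: np.ndarray, mask_a: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
        idx_a = np.flatnonzero(mask_a)
        idx_b = np.flatnonzero(~mask_a)
        n_a = max(2, int(np.ceil(self.subsample * idx_a.size)))
        n_b = max(2, int(np.ceil(self.subsample * idx_b.size)))
        eff = np.zeros(block.shape[1])
        used = 0
        for _ in range(self.n_boot):
            sub = np.concatenate([
                rng.choice(idx_a, size=min(n_a, idx_a.size), replace=False),
                rng.choice(idx_b, size=min(n_b, idx_b.size), replace=False),
            ])
            xb = block[sub]
            yb = mask_a[sub]
            raw_diff = np.abs(xb[yb].mean(axis=0) - xb[~yb].mean(axis=0))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lda = LinearDiscriminantAnalysis(solver="svd").fit(xb, yb)
                w = lda.coef_[0]
            except Exception:  # degenerate subsample
                continue
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            w_u = w / norm
            proj = xb @ w_u
            axis_gap = abs(proj[yb].mean() - proj[~yb].mean())
            eff += (raw_diff + np.abs(w_u) * axis_gap) / 2.0
            used += 1
        if used == 0:
            return np.full(block.shape[1], -np.inf)
        eff /= used
        with np.errstate(divide="ignore"):
            return np.log10(np.maximum(eff, 1e-30))

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def to_discriminant_set(self) -> DiscriminantSet:
        check_is_fitted(self, "support_")
        keep = self.support_
        frame = pd.DataFrame(
            {
                "direction": self.directions_[keep],
                "p_value": self.pvalues_[keep],
                "score": self.scores_[keep],
                "stage": "lefse",
            },
            index=pd.Index(self.feature_names_in_[keep], name="feature"),
        )
        return DiscriminantSet(frame, self.alpha)


def lefse(table, classes, alpha: float = 0.05, lda_threshold: float = 2.0,
          n_boot: int = 30, seed: int | None = None) -> DiscriminantSet:
    """Functional wrapper around :class:`LefseSelector`."""
    values = table.values if hasattr(table, "values") and hasattr(table, "kind") else table
    sel = LefseSelector(alpha=alpha, lda_threshold=lda_threshold,
                        n_boot=n_boot, random_state=seed)
    sel.fit(values, classes)
    return sel.to_discriminant_set()


def pathway_screen(table, classes, mean_threshold: float = 0.01,
                   alpha: float = 0.05) -> DiscriminantSet:
    """Exact rank-sum screen of pathways whose global mean exceeds the gate."""
    values = table.values if hasattr(table, "kind") else _as_frame(table)
    y, cls = _two_classes(classes)
    mask_a = y == cls[0]
    arr = values.to_numpy(dtype=float)
    tested = np.flatnonzero(arr.mean(axis=0) > mean_threshold)
    rows = []
    for j in tested:
        u, p = exact_rank_sum(arr[mask_a, j], arr[~mask_a, j])
        if p < alpha:
            rows.append((values.columns[j],
                         _direction(arr[:, j], mask_a, str(cls[0]), str(cls[1])),
                         p))
    frame = pd.DataFrame(
        rows, columns=["feature", "direction", "p_value"]
    ).set_index("feature") if rows else pd.DataFrame(
        columns=["direction", "p_value"], index=pd.Index([], name="feature")
    )
    frame["score"] = np.nan
    frame["stage"] = "pathway_screen"
    return DiscriminantSet(frame[["direction", "p_value", "score", "stage"]], alpha)


def _soft_threshold_keepx(w: np.ndarray, keep_x: int) -> np.ndarray:
    p = w.size
    if keep_x >= p:
        return w
    absw = np.abs(w)
    lam = np.partition(absw, p - keep_x - 1)[p - keep_x - 1]
    return np.sign(w) * np.maximum(absw - lam, 0.0)


class SparsePLSDA(BaseEstimator, TransformerMixin):
    """Sparse PLS discriminant analysis with per-component cardinality keepX.

    NIPALS on the autoscaled data against a centered/scaled class-indicator
    matrix; each loading-weight vector is soft-thresholded so that exactly
    ``keep_x`` entries stay non-zero (the cardinality convention), then
    renormalized to unit length. With ``keep_x >= n_features`` the model is
    dense PLS-DA.
    """

    def __init__(self, n_components: int = 2, keep_x: int = 100,
                 scale: bool = True, max_iter: int = 500, tol: float = 1e-10,
                 random_state: int | None = None):
        self.n_components = n_components
        self.keep_x = keep_x
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        frame = _as_frame(X)
        y, classes = _two_classes(y)
        n, p = frame.shape
        if self.keep_x > p:
            logger.info("keep_x=%d exceeds n_features=%d; dense PLS-DA",
                        self.keep_x, p)
        Xv = frame.to_numpy(dtype=float)
        self._x_mean = Xv.mean(axis=0)
        sd = Xv.std(axis=0, ddof=1)
        self._x_std = np.where(sd > 0, sd, 1.0) if self.scale else np.ones(p)
        Xc = (Xv - self._x_mean) / self._x_std

        Y = np.column_stack([(y == c).astype(float) for c in classes])
        self._y_mean = Y.mean(axis=0)
        ysd = Y.std(axis=0, ddof=1)
        self._y_std = np.where(ysd > 0, ysd, 1.0)
        Yc = (Y - self._y_mean) / self._y_std

        W = np.zeros((p, self.n_components))   # x loading weights
        Pl = np.zeros((p, self.n_components))  # x loadings
        Q = np.zeros((Y.shape[1], self.n_components))
        T = np.zeros((n, self.n_components))
        kept = []
        Xr, Yr = Xc.copy(), Yc.copy()
        for k in range(self.n_components):
            u = Yr[:, [np.argmax(Yr.var(axis=0))]].ravel()
            w_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                w = _soft_threshold_keepx(w, self.keep_x)
                norm = np.linalg.norm(w)
                if norm == 0:
                    raise ValueError("all loading weights thresholded to zero")
                w /= norm
                t = Xr @ w
                q = Yr.T @ t / (t @ t)
                u = Yr @ q / (q @ q)
                if w_old is not None and np.linalg.norm(w - w_old) < self.tol:
                    break
                w_old = w
            t = Xr @ w
            pl = Xr.T @ t / (t @ t)
            q = Yr.T @ t / (t @ t)
            Xr = Xr - np.outer(t, pl)
            Yr = Yr - np.outer(t, q)
            W[:, k], Pl[:, k], Q[:, k], T[:, k] = w, pl, q, t
            kept.append(np.flatnonzero(w))

        self.feature_names_in_ = np.asarray(frame.columns)
        self.classes_ = classes
        self.x_weights_ = W
        self.x_loadings_ = Pl
        self.y_loadings_ = Q
        self.x_scores_ = T
        self.kept_ = kept
        self.kept_features_ = [list(self.feature_names_in_[k]) for k in kept]
        # rotation for single-pass transform of new data
        self.x_rotations_ = W @ np.linalg.pinv(Pl.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T
        return self

    def transform(self, X):
        check_is_fitted(self, "x_rotations_")
        Xv = _as_frame(X).to_numpy(dtype=float)
        return ((Xv - self._x_mean) / self._x_std) @ self.x_rotations_

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xv = _as_frame(X).to_numpy(dtype=float)
        yhat = ((Xv - self._x_mean) / self._x_std) @ self.coef_
        yhat = yhat * self._y_std + self._y_mean
        return self.classes_[np.argmax(yhat, axis=1)]

    @property
    def selected_features_(self) -> list[str]:
        """Union of kept variables across components, in feature order."""
        check_is_fitted(self, "kept_")
        mask = np.zeros(len(self.feature_names_in_), dtype=bool)
        for k in self.kept_:
            mask[k] = True
        return list(self.feature_names_in_[mask])


def log_autoscale(frame: pd.DataFrame, unit_variance: bool = True) -> pd.DataFrame:
    """Median-scale per feature, log-transform, optionally autoscale."""
    med = frame.median(axis=0)
    if (med <= 0).any():
        raise ValueError("non-positive feature medians; cannot median-scale")
    logged = np.log(frame / med)
    if not unit_variance:
        return logged
    sd = logged.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (logged - logged.mean(axis=0)) / sd


def fit_splsda(table, classes, n_components: int = 2, keep_x: int = 100,
               seed: int | None = None) -> SparsePLSDA:
    """Fit sPLS-DA on log-median-scaled metabolite intensities."""
    frame = table.values if hasattr(table, "kind") else _as_frame(table)
    prepped = log_autoscale(frame, unit_variance=False)
    model = SparsePLSDA(n_components=n_components, keep_x=keep_x,
                        random_state=seed)
    model.fit(prepped, classes)
    return model


def splsda_wilcoxon_filter(model: SparsePLSDA, table, classes,
                           alpha: float = 0.05) -> DiscriminantSet:
    """Exact rank-sum test on the sPLS-DA kept variables; retain p < alpha.

    No multiplicity adjustment is applied at this stage; the two-stage gate
    (loading-based shortlist, then raw p < alpha) is the selection rule.
    """
    check_is_fitted(model, "kept_")
    frame = table.values if hasattr(table, "kind") else _as_frame(table)
    y, cls = _two_classes(classes)
    mask_a = y == cls[0]
    arr = frame.to_numpy(dtype=float)
    weights = np.abs(model.x_weights_).max(axis=1)
    name_to_col = {f: j for j, f in enumerate(frame.columns)}
    rows = []
    for feat in model.selected_features_:
        j = name_to_col[feat]
        _, p = exact_rank_sum(arr[mask_a, j], arr[~mask_a, j])
        if p < alpha:
            widx = int(np.flatnonzero(model.feature_names_in_ == feat)[0])
            rows.append((feat,
                         _direction(arr[:, j], mask_a, str(cls[0]), str(cls[1])),
                         p, weights[widx]))
    frame_out = pd.DataFrame(
        rows, columns=["feature", "direction", "p_value", "score"]
    ).set_index("feature") if rows else pd.DataFrame(
        columns=["direction", "p_value", "score"], index=pd.Index([], name="feature")
    )
    frame_out["stage"] = "splsda_wilcoxon"
    return DiscriminantSet(frame_out[["direction", "p_value", "score", "stage"]], alpha)


class Pc1Selector(BaseEstimator):
    """Signed PC1-loading selection of the top discriminant metabolites.

    PCA on the autoscaled discriminant-metabolite block; the PC1 axis is
    oriented so the Lower-group mean score is positive, making positive
    loadings the Lower-elevated side. Loadings are reported in the
    factor-analytic convention — the correlation between each metabolite and
    the PC1 score — which keeps fixed thresholds meaningful regardless of
    how many metabolites enter the PCA (unit-norm eigenvector entries shrink
    as 1/sqrt(n_features) and would make any fixed cutoff panel-size
    dependent). Features with loading > ``upper`` form the positive set,
    loading < ``lower`` the negative set.
    """

    def __init__(self, upper: float = 0.15, lower: float = -0.10,
                 lower_label: str = "Lower"):
        self.upper = upper
        self.lower = lower
        self.lower_label = lower_label

    def fit(self, X, y):
        frame = _as_frame(X)
        if frame.shape[1] < 2:
            raise ValueError("PC1 selection needs at least 2 features")
        y = np.asarray(y)
        Xv = frame.to_numpy(dtype=float)
        sd = Xv.std(axis=0, ddof=1)
        Xs = (Xv - Xv.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        pca = PCA(n_components=1)
        scores = pca.fit_transform(Xs).ravel()
        if scores[y == self.lower_label].mean() < scores[y != self.lower_label].mean():
            scores = -scores
        # correlation loadings: corr(feature, PC1 score), sign included
        sc = scores - scores.mean()
        denom = np.linalg.norm(sc) * np.sqrt((Xs**2).sum(axis=0))
        loadings = (Xs.T @ sc) / np.where(denom > 0, denom, 1.0)
        self.feature_names_in_ = np.asarray(frame.columns)
        self.loadings_ = loadings
        self.scores_ = scores
        self.explained_variance_ratio_ = float(pca.explained_variance_ratio_[0])
        if self.explained_variance_ratio_ < 0.20:
            warnings.warn(
                f"PC1 explains only {self.explained_variance_ratio_:.1%} of variance",
                stacklevel=2,
            )
        self.positive_ = list(self.feature_names_in_[loadings > self.upper])
        self.negative_ = list(self.feature_names_in_[loadings < self.lower])
        return self


def pca_pc1_select(table, classes, upper: float = 0.15,
                   lower: float = -0.10) -> Pc1Selector:
    """PC1 selection on log-median-scaled discriminant metabolites."""
    frame = table.values if hasattr(table, "kind") else _as_frame(table)
    prepped = log_autoscale(frame, unit_variance=False)
    return Pc1Selector(upper=upper, lower=lower).fit(prepped, classes)


def hca(values) -> tuple[np.ndarray, list]:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    Returns the scipy linkage matrix and the dendrogram leaf order (row
    labels). Rows of ``values`` are the objects being clustered; autoscale
    beforehand for the heatmap convention.
    """
    frame = _as_frame(values) if not isinstance(values, pd.DataFrame) else values
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(frame.to_numpy(dtype=float), method="ward", metric="euclidean")
    order = [frame.index[i] for i in leaves_list(Z)]
    return Z, order
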