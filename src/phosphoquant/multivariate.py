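"""NIPALS PLS-DA / PCA for QC of the multivariate intensity and ratio data.

The model is used two ways in the pipeline:

* *intensity QC* — rows are labelled samples (plex × arm × channel), columns
  are peptide features, values are log2 reporter intensities; PLS-DA against
  the tissue class shows whether T and NT separate and whether any sample is
  an outlier (Hotelling T² 95% limit);
* *ratio QC* — rows are cases, columns are merged phosphopeptide log2 T/NT
  ratios; unsupervised (PCA mode) grouping of cases.

The estimator follows the scikit-learn idiom (``fit`` / ``transform``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) but
implements NIPALS directly so that missing cells can be skipped pairwise in
every inner product — the ratio matrix has structural absences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PhosphoQuantError

MISSING_POLICIES = ("pairwise", "drop-variable")


def hotelling_t2_limit(n_samples: int, n_components: int, alpha: float = 0.05) -> float:
    """Upper control limit of Hotelling's T² at confidence 1 - alpha.

    limit = k (n - 1) / (n - k) * F_{1-alpha}(k, n - k), with k components
    fitted on n samples.  Requires n > k.
    """
    n, k = int(n_samples), int(n_components)
    if n <= k:
        raise PhosphoQuantError(
            f"hotelling_t2_limit requires n_samples > n_components (got {n} <= {k})"
        )
    return float(k * (n - 1) / (n - k) * stats.f.isf(alpha, k, n - k))


class NipalsPLS:
    """NIPALS partial-least-squares discriminant analysis / PCA.

    Parameters
    ----------
    n_components : number of latent components to extract.
    scale : divide columns by their standard deviation after centering
        (default off: mean-centering only).
    missing_policy : ``"pairwise"`` skips missing cells inside the NIPALS
        inner products; ``"drop-variable"`` drops any column with a missing
        value before fitting.
    max_iter, tol : inner-loop convergence control.
    alpha : confidence level complement for the Hotelling T² limit.

    Fitted attributes
    -----------------
    x_scores_ : (samples × components) score matrix, columns orthogonal.
    x_loadings_ : (variables × components) loadings.
    x_weights_ : (variables × components) PLS weights (equal to loadings in
        PCA mode).
    explained_variance_ratio_ : per-component fraction of the centered X
        sum of squares.
    classes_, y_ : class labels (PLS-DA mode only).
    t2_limit_95_ : Hotelling T² limit for the fitted scores.
    mode_ : ``"plsda"`` or ``"pca"``.
    """

    def __init__(
        self,
        n_components: int = 2,
        scale: bool = False,
        missing_policy: str = "pairwise",
        max_iter: int = 2000,
        tol: float = 1e-12,
        alpha: float = 0.05,
    ):
        self.n_components = n_components
        self.scale = scale
        self.missing_policy = missing_policy
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    # -- sklearn-style parameter plumbing ---------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "scale": self.scale,
            "missing_policy": self.missing_policy,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "alpha": self.alpha,
        }

    def set_params(self, **params) -> "NipalsPLS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def _prepare(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.arange(X.shape[1])
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(
                f"unknown missing_policy {self.missing_policy!r}; "
                f"choose from {MISSING_POLICIES}"
            )
        if self.missing_policy == "drop-variable":
            keep = np.isfinite(X).all(axis=0)
            X = X[:, keep]
            self.feature_names_in_ = self.feature_names_in_[keep]
        mask = np.isfinite(X)
        if not mask.any(axis=0).all():
            # a variable never observed carries no information
            keep = mask.any(axis=0)
            X = X[:, keep]
            mask = mask[:, keep]
            self.feature_names_in_ = self.feature_names_in_[keep]
        return X, mask

    def fit(self, X, y=None) -> "NipalsPLS":
        X, mask = self._prepare(X)
        n, m = X.shape
        if n < 2 or m < 1:
            raise PhosphoQuantError("need at least 2 samples and 1 variable")
        with np.errstate(invalid="ignore"):
            Xm = np.where(mask, X, np.nan)
            self.x_mean_ = np.nanmean(Xm, axis=0)
            sd = np.nanstd(Xm, axis=0, ddof=0)
        self.x_std_ = np.where(sd > 0, sd, 1.0) if self.scale else np.ones(m)
        Xc = np.where(mask, (X - self.x_mean_) / self.x_std_, 0.0)
        total_ss = float((Xc**2).sum())
        if total_ss == 0.0:
            raise PhosphoQuantError("all variables are constant; nothing to model")

        if y is not None:
            y = np.asarray(y)
            self.classes_ = np.unique(y)
            if self.classes_.size < 2:
                raise PhosphoQuantError("PLS-DA needs at least 2 classes")
            if self.classes_.size == 2:
                Y = (y == self.classes_[1]).astype(float)[:, None]
            else:
                Y = (y[:, None] == self.classes_[None, :]).astype(float)
            Y = Y - Y.mean(axis=0)
            self.y_ = y
            self.mode_ = "plsda"
        else:
            Y = None
            self.mode_ = "pca"

        k = min(self.n_components, n - 1, m)
        W = mask.astype(float)
        scores = np.zeros((n, k))
        loadings = np.zeros((m, k))
        weights = np.zeros((m, k))
        explained = np.zeros(k)
        Yres = None if Y is None else Y.copy()

        for comp in range(k):
            t, p, w = self._extract_component(Xc, W, Yres)
            # sign convention: largest-|loading| entry positive
            j = int(np.argmax(np.abs(p)))
            if p[j] < 0:
                t, p, w = -t, -p, -w
            scores[:, comp] = t
            loadings[:, comp] = p
            weights[:, comp] = w
            # explained SS over observed cells of the rank-1 reconstruction
            explained[comp] = float((t**2) @ W @ (p**2))
            Xc = Xc - np.outer(t, p) * W
            if Yres is not None:
                tt = float(t @ t)
                if tt > 0:
                    q = Yres.T @ t / tt
                    Yres = Yres - np.outer(t, q)

        self.x_scores_ = scores
        self.x_loadings_ = loadings
        self.x_weights_ = weights
        self.explained_variance_ratio_ = explained / total_ss
        self.total_ss_ = total_ss
        self.residual_ss_ = float((Xc**2).sum())
        self.n_samples_ = n
        self.n_components_ = k
        self.t2_limit_95_ = (
            hotelling_t2_limit(n, k, self.alpha) if n > k else float("nan")
        )
        return self

    def _extract_component(self, Xc, W, Yres):
        """One NIPALS component; pairwise-missing inner products throughout."""
        n, m = Xc.shape
        if Yres is None:
            # PCA mode: start from the column with the largest sum of squares
            t = Xc[:, int(np.argmax((Xc**2).sum(axis=0)))].copy()
            if not np.any(t):
                t = Xc[:, 0] + 1e-12
            for _ in range(self.max_iter):
                denom = W.T @ (t**2)
                p = (Xc.T @ t) / np.where(denom > 0, denom, 1.0)
                norm = np.linalg.norm(p)
                if norm == 0:
                    break
                p /= norm
                denom = W @ (p**2)
                t_new = (Xc @ p) / np.where(denom > 0, denom, 1.0)
                if np.linalg.norm(t_new - t) <= self.tol * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    break
                t = t_new
            denom = W.T @ (t**2)
            p = (Xc.T @ t) / np.where(denom > 0, denom, 1.0)
            return t, p, p.copy()
        # PLS-DA mode
        u = Yres[:, int(np.argmax((Yres**2).sum(axis=0)))].copy()
        if not np.any(u):
            u = np.ones(n)
        w = np.zeros(m)
        t = np.zeros(n)
        for _ in range(self.max_iter):
            denom = W.T @ (u**2)
            w = (Xc.T @ u) / np.where(denom > 0, denom, 1.0)
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            denom = W @ (w**2)
            t_new = (Xc @ w) / np.where(denom > 0, denom, 1.0)
            tt = float(t_new @ t_new)
            q = Yres.T @ t_new / tt if tt > 0 else np.zeros(Yres.shape[1])
            qq = float(q @ q)
            u_new = Yres @ q / qq if qq > 0 else u
            if np.linalg.norm(t_new - t) <= self.tol * max(np.linalg.norm(t_new), 1e-300):
                t, u = t_new, u_new
                break
            t, u = t_new, u_new
        denom = W.T @ (t**2)
        p = (Xc.T @ t) / np.where(denom > 0, denom, 1.0)
        return t, p, w

    # -- application -------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Project new rows onto the fitted components (pairwise-missing)."""
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.feature_names_in_).to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        mask = np.isfinite(X)
        Xc = np.where(mask, (X - self.x_mean_) / self.x_std_, 0.0)
        W = mask.astype(float)
        scores = np.zeros((X.shape[0], self.n_components_))
        for comp in range(self.n_components_):
            p = self.x_loadings_[:, comp]
            w = self.x_weights_[:, comp]
            denom = W @ (w**2)
            t = (Xc @ w) / np.where(denom > 0, denom, 1.0)
            scores[:, comp] = t
            Xc = Xc - np.outer(t, p) * W
        return scores

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).x_scores_

    def hotelling_t2(self) -> np.ndarray:
        """Per-sample Hotelling T² of the fitted scores."""
        t = self.x_scores_
        var = t.var(axis=0, ddof=1)
        var = np.where(var > 0, var, np.inf)
        return (t**2 / var).sum(axis=1)


def intensity_matrix(
    records,
    design,
    level: str = "feature",
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample × variable log2-intensity matrix for the intensity QC analysis.

    Rows are (plex, arm, channel) samples labelled by tissue.  With
    ``level="feature"`` (default) the variables are peptide feature keys and
    each cell is the median log2 intensity of the feature's PSMs in that
    (plex, arm) — features observed in several plexes align into one column.
    With ``level="psm"`` the variables are individual PSM ids (each observed
    in a single plex, so the matrix is mostly missing across plexes).

    Returns (matrix, tissue labels per row).
    """
    from .psm import feature_key as fkey

    rows: dict[tuple, dict] = {}
    for rec in records:
        var = rec.psm_id if level == "psm" else fkey(rec)
        for ch, v in rec.intensities.items():
            if v is None or v <= 0:
                continue
            key = (rec.plex, rec.arm, ch)
            rows.setdefault(key, {}).setdefault(var, []).append(np.log2(v))
    sample_keys = sorted(rows)
    all_vars = sorted({v for d in rows.values() for v in d})
    mat = np.full((len(sample_keys), len(all_vars)), np.nan)
    var_index = {v: j for j, v in enumerate(all_vars)}
    for i, key in enumerate(sample_keys):
        for var, vals in rows[key].items():
            mat[i, var_index[var]] = float(np.median(vals))
    index = pd.MultiIndex.from_tuples(sample_keys, names=["plex", "arm", "channel"])
    frame = pd.DataFrame(mat, index=index, columns=all_vars)
    tissues = pd.Series(
        [design.case_of(p, c)[1] for p, _a, c in sample_keys], index=index, name="tissue"
    )
    return frame, tissues
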