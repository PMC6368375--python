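"""Multivariate analysis: PCA outlier screening and PLS-DA classification.

PCA is fitted by SVD of the column-mean-centered matrix (equivalent to a
converged NIPALS, but deterministic) and feeds a Hotelling T2 outlier
screen.  PLS-DA is a NIPALS PLS1 against the centered 0/1 class coding
(TN -> 0, HS -> 1); model quality is summarised by R2X (fraction of the
centered X sum of squares captured by the score/loading reconstruction),
R2Y (fraction of class variance explained) and the leave-one-out
cross-validated Q2 = 1 - PRESS/TSS.  Model significance is tested by
permuting class labels and recomputing Q2; biomarker candidates are the
bins whose first-component loadings exceed a magnitude threshold.

Mean-centering is the only scaling applied: the features are already
log2-transformed creatinine-normalized intensities.  Cross-validation
re-centers inside every training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    InvalidParameterError,
)
from .preprocess import FeatureMatrix

__all__ = [
    "PCAModel",
    "PLSModel",
    "PermutationResult",
    "pca_fit",
    "hotelling_t2",
    "hotelling_outliers",
    "plsda_fit",
    "loo_q2",
    "permutation_test_q2",
    "select_biomarkers_by_loading",
]


def _as_xy(X, y=None):
    """Accept a FeatureMatrix or a plain array (+ explicit y)."""
    if isinstance(X, FeatureMatrix):
        arr = X.x
        centers = X.bin_centers
        if y is None:
            y = X.y
    else:
        arr = np.asarray(X, dtype=float)
        centers = None
    if y is not None:
        y = _code_classes(np.asarray(y))
    return arr, y, centers


def _code_classes(y: np.ndarray) -> np.ndarray:
    """Map a two-level label vector onto {0, 1}; TN -> 0 and HS -> 1."""
    if y.dtype.kind in "fiub":
        vals = np.unique(y)
        if not np.all(np.isin(vals, (0, 1))):
            raise DesignError(f"numeric class vector must be 0/1, got {vals}")
        return y.astype(float)
    labels = np.unique(y)
    if set(labels) == {"TN", "HS"}:
        return (y == "HS").astype(float)
    if len(labels) != 2:
        raise DesignError(f"exactly two classes required, got {list(labels)}")
    return (y == labels[1]).astype(float)


# ----------------------------------------------------------------- PCA

@dataclass
class PCAModel:
    means: np.ndarray
    loadings: np.ndarray              # bins x components, orthonormal
    scores: np.ndarray                # samples x components
    explained_variance_fraction: np.ndarray
    bin_centers: np.ndarray | None = None


def pca_fit(X, n_components: int = 2) -> PCAModel:
    """PCA by SVD of the centered matrix; component signs are fixed by
    making each component's largest-magnitude loading positive."""
    arr, _, centers = _as_xy(X)
    n, p = arr.shape
    if n_components < 1 or n_components > min(n - 1, p):
        raise InvalidParameterError(
            f"n_components must be in 1..{min(n - 1, p)}"
        )
    xc = arr - arr.mean(axis=0)
    total_ss = float((xc**2).sum())
    if total_ss == 0:
        raise DegenerateInputError("constant matrix: nothing to decompose")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for a in range(n_components):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    return PCAModel(
        means=arr.mean(axis=0),
        loadings=vt.T,
        scores=u * s,
        explained_variance_fraction=s**2 / total_ss,
        bin_centers=centers,
    )


def hotelling_t2(scores: np.ndarray, alpha: float = 0.05):
    """Hotelling T2 of score rows against the F-based control limit.

    T2_i = sum_a t_ia^2 / var(t_a);  limit = A(n-1)(n+1) / (n(n-A)) *
    F(1-alpha; A, n-A).  Returns (t2, limit, flags).
    """
    scores = np.asarray(scores, dtype=float)
    n, a_comp = scores.shape
    if a_comp < 2:
        raise InvalidParameterError("need at least 2 components for the T2 screen")
    if n <= a_comp + 1:
        raise InsufficientDataError("too few samples for the T2 limit")
    var = scores.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise DegenerateInputError("a score column has zero variance")
    t2 = ((scores - scores.mean(axis=0)) ** 2 / var).sum(axis=1)
    limit = (
        a_comp * (n - 1) * (n + 1) / (n * (n - a_comp))
        * stats.f.ppf(1 - alpha, a_comp, n - a_comp)
    )
    return t2, float(limit), t2 > limit


def hotelling_outliers(m: PCAModel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample T2 screen on a fitted PCA model (95% limit by default)."""
    t2, limit, flags = hotelling_t2(m.scores, alpha)
    return pd.DataFrame({"t2": t2, "limit": limit, "outlier": flags})


# --------------------------------------------------------------- PLS-DA

@dataclass
class PLSModel:
    x_means: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x A
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A
    scores: np.ndarray        # n x A
    r2x: np.ndarray           # per component
    r2x_cum: float
    r2y_cum: float
    n_components: int
    bin_centers: np.ndarray | None = None
    q2: float | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b with y_hat = y_mean + (x - x_means) @ b."""
        w, p, q = self.weights, self.x_loadings, self.y_loadings
        return w @ np.linalg.solve(p.T @ w, q)

    def predict(self, X) -> np.ndarray:
        arr = X.x if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return self.y_mean + (arr - self.x_means) @ self.coef


def _nipals_pls1(xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered data; returns (W, P, q, T).

    With a univariate response the weight update w = X'y / ||X'y|| is the
    NIPALS fixed point, so each component needs a single pass.
    """
    n, p = xc.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    x = xc.copy()
    y = yc.copy()
    for a in range(n_components):
        w = x.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateInputError(
                f"component {a + 1}: response uncorrelated with all residual bins"
            )
        w /= norm
        t = x @ w
        tt = float(t @ t)
        if tt == 0:
            raise DegenerateInputError(f"component {a + 1}: zero score vector")
        pvec = x.T @ t / tt
        qa = float(y @ t) / tt
        x = x - np.outer(t, pvec)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    return W, P, q, T


def plsda_fit(X, y=None, n_components: int = 2) -> PLSModel:
    """Fit a PLS-DA model (NIPALS PLS1 on centered X and centered 0/1 y).

    Component 1 is oriented so that the HS class (coded 1) has positive
    mean score, which makes positive loadings read as "higher under HS".
    """
    arr, yv, centers = _as_xy(X, y)
    if yv is None:
        raise DesignError("a class vector is required")
    n, p = arr.shape
    if yv.shape[0] != n:
        raise DesignError("y length does not match X rows")
    if len(np.unique(yv)) != 2:
        raise DesignError("exactly two classes must be present")
    if n_components < 1:
        raise InvalidParameterError("n_components must be >= 1")
    x_means = arr.mean(axis=0)
    y_mean = float(yv.mean())
    xc = arr - x_means
    yc = yv - y_mean
    ssx = float((xc**2).sum())
    ssy = float((yc**2).sum())
    W, P, q, T = _nipals_pls1(xc, yc, n_components)
    # orient component 1: positive mean score for the HS class
    if T[yv == 1, 0].mean() < 0:
        W[:, 0] *= -1.0
        P[:, 0] *= -1.0
        q[0] *= -1.0
        T[:, 0] *= -1.0
    tt = (T**2).sum(axis=0)
    r2x = tt * (P**2).sum(axis=0) / ssx
    resid = yc - T @ q
    r2y_cum = 1.0 - float(resid @ resid) / ssy
    return PLSModel(
        x_means=x_means,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        r2x=r2x,
        r2x_cum=float(r2x.sum()),
        r2y_cum=r2y_cum,
        n_components=n_components,
        bin_centers=centers,
    )


def _compress_rows(arr: np.ndarray) -> np.ndarray:
    """Project X onto an orthonormal basis of its row space (exact).

    Every PLS1 quantity that the cross-validation and permutation loops
    report (scores, predictions, Q2, R2) depends on X only through row
    inner products, and fold-wise centering keeps rows inside the original
    row span, so replacing X (n x p) by U*S (n x r) from its SVD changes
    nothing while shrinking p to at most n.
    """
    n, p = arr.shape
    if p <= n:
        return arr
    u, s, _ = np.linalg.svd(arr, full_matrices=False)
    return u * s


def loo_q2(X, y=None, n_components: int = 2, compress: bool = True) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS/TSS.

    Each fold refits the model from scratch on the remaining samples,
    re-centering X and y inside the fold; TSS uses the full-data centered y.
    """
    arr, yv, _ = _as_xy(X, y)
    if yv is None:
        raise DesignError("a class vector is required")
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError("leave-one-out needs at least 3 samples")
    if compress:
        arr = _compress_rows(arr)
    press = 0.0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        xtr, ytr = arr[tr], yv[tr]
        xm = xtr.mean(axis=0)
        ym = ytr.mean()
        W, P, q, _ = _nipals_pls1(xtr - xm, ytr - ym, n_components)
        b = W @ np.linalg.solve(P.T @ W, q)
        y_hat = ym + (arr[i] - xm) @ b
        press += (y_hat - yv[i]) ** 2
    tss = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    observed_q2: float
    permuted_q2: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


def permutation_test_q2(
    X,
    y=None,
    n_components: int = 2,
    n_permutations: int = 1000,
    seed: int | None = None,
    design: pd.DataFrame | None = None,
) -> PermutationResult:
    """Compare the observed LOO Q2 against a label-permutation null.

    Labels are permuted freely by default; passing the crossover ``design``
    restricts permutations to within-animal swaps.  The p-value uses the
    add-one formula (count(permuted >= observed) + 1) / (n + 1).
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    arr, yv, _ = _as_xy(X, y)
    arr = _compress_rows(arr)
    rng = np.random.default_rng(seed)
    observed = loo_q2(arr, yv, n_components, compress=False)
    permuted = np.empty(n_permutations)
    if design is not None:
        animals = design["animal_id"].to_numpy()
        uniq = np.unique(animals)
    for k in range(n_permutations):
        if design is None:
            y_perm = rng.permutation(yv)
        else:
            y_perm = yv.copy()
            flip = uniq[rng.random(uniq.size) < 0.5]
            for a in flip:
                sel = animals == a
                y_perm[sel] = 1.0 - y_perm[sel]
        permuted[k] = loo_q2(arr, y_perm, n_components, compress=False)
    p = (float((permuted >= observed).sum()) + 1.0) / (n_permutations + 1.0)
    return PermutationResult(
        observed_q2=observed,
        permuted_q2=permuted,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def select_biomarkers_by_loading(
    m: PLSModel,
    threshold: float = 0.0005,
    bin_centers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bins whose |component-1 loading| exceeds ``threshold``, ranked by
    magnitude (descending).  Positive loadings mean higher under HS.

    The threshold applies to the normalized/log2 matrix the model was
    fitted on; loadings are not scale-invariant.
    """
    p1 = m.x_loadings[:, 0]
    centers = bin_centers if bin_centers is not None else m.bin_centers
    if centers is None:
        centers = np.arange(p1.size, dtype=float)
    df = pd.DataFrame({"ppm": np.asarray(centers, dtype=float), "loading": p1})
    df["abs_loading"] = df["loading"].abs()
    df = df[df["abs_loading"] > threshold]
    df = df.sort_values("abs_loading", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
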