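"""Multivariate discrimination of organic vs conventional cohorts.

Implements the chemometrics workflow on bucketed spectra: total-methyl
normalization (NorCont), Pareto scaling, PCA, a NIPALS PLS-DA written here
(not delegated), VIP scores, segmented cross-validation with Q2, a
two-sided Fisher exact test on the pooled out-of-fold confusion matrix,
label-permutation validation, Hotelling-T2 outlier flagging and per-bucket
two-sample t-tests.

The PLS-DA follows the model/results idiom: :class:`PLSDA` is built from a
data matrix and class labels, ``fit()`` returns a :class:`PLSDAResults`
carrying scores, loadings, R2Y and VIP, and cross-validation / permutation
validation hang off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import IntegrationWindow, default_windows

__all__ = [
    "BucketMatrix",
    "methyl_bucket_mask",
    "normalize_norcont",
    "pareto_scale",
    "pca",
    "PCAResults",
    "PLSDA",
    "PLSDAResults",
    "ValidationReport",
    "PermutationResult",
    "plsda_fit",
    "plsda_cv",
    "vip",
    "permutation_test",
    "fisher_exact_2x2",
    "hotelling_outliers",
    "marker_ttest",
]


# ---------------------------------------------------------------------------
# bucket matrix and preprocessing

@dataclass
class BucketMatrix:
    """Samples x buckets matrix with class labels.

    ``values`` is a DataFrame indexed by sample id with bucket centers
    (ppm) as columns; ``normalization_tag`` is ``"UNor"`` (raw areas) or
    ``"NorCont"`` (total-methyl normalized).
    """

    values: pd.DataFrame
    class_labels: list
    group: str = ""
    normalization_tag: str = "UNor"

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("bucket matrix contains NaN")
        if len(self.class_labels) != len(self.values):
            raise ValueError("one class label per sample required")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    #: ppm regions masked before multivariate analysis: the internal
    #: chemical-shift reference (0.172 ppm) is not a lipid signal and its
    #: fixed amount anti-scales with lipid content after NorCont.
    DEFAULT_EXCLUDE = ((0.12, 0.22),)

    @staticmethod
    def from_spectra(spectra, class_labels, sample_ids=None, group: str = "",
                     exclude_regions=DEFAULT_EXCLUDE) -> "BucketMatrix":
        """Bucket spectra into a matrix; excluded regions are zeroed.

        Zeroed buckets keep the 631-column layout but become constant, so
        Pareto scaling removes them from the multivariate model.
        """
        from .processing import bucket
        rows = [bucket(s) for s in spectra]
        centers = rows[0].centers
        ids = sample_ids or [f"s{i:03d}" for i in range(len(rows))]
        values = np.array([r.values for r in rows])
        for lo, hi in (exclude_regions or ()):
            values[:, (centers >= lo) & (centers < hi)] = 0.0
        df = pd.DataFrame(values, index=ids, columns=np.round(centers, 4))
        return BucketMatrix(df, list(class_labels), group=group)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "class", list(self.class_labels))
        out.to_csv(path, index_label="sample_id")

    @staticmethod
    def from_csv(path, normalization_tag: str = "UNor") -> "BucketMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        labels = df.pop("class").tolist()
        df.columns = df.columns.astype(float)
        return BucketMatrix(df, labels, normalization_tag=normalization_tag)


def methyl_bucket_mask(centers, windows: list[IntegrationWindow] | None = None) -> np.ndarray:
    """Boolean mask of buckets lying in the methyl windows (I0.88 + I0.95)."""
    windows = windows if windows is not None else default_windows()
    methyl = [w for w in windows if w.name in ("I0.88", "I0.95")]
    centers = np.asarray(centers, dtype=float)
    mask = np.zeros(centers.size, dtype=bool)
    for w in methyl:
        mask |= (centers >= w.lo_ppm) & (centers < w.hi_ppm)
    return mask


def normalize_norcont(matrix: BucketMatrix,
                      methyl_mask: np.ndarray | None = None) -> BucketMatrix:
    """Total-methyl ("NorCont") normalization: row scaled by 3 / I_TL.

    I_TL(i) is the sum of the sample's methyl-region buckets, so every
    bucket becomes a per-one-proton % content of the lipid fraction and
    per-sample total-lipid differences cancel.
    """
    mask = methyl_mask if methyl_mask is not None else methyl_bucket_mask(matrix.centers)
    X = matrix.to_array()
    itl = X[:, mask].sum(axis=1)
    bad = np.nonzero(itl <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive methyl sum for sample(s) {[matrix.values.index[i] for i in bad]}")
    scaled = X * (3.0 / itl)[:, None]
    df = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    return BucketMatrix(df, list(matrix.class_labels), group=matrix.group,
                        normalization_tag="NorCont")


def pareto_scale(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and divide by the square root of the column sd.

    Returns ``(scaled, means, sds)``; constant columns map to zero. Pareto
    scaling damps large-variance buckets less aggressively than unit
    variance scaling, keeping the data close to their original values.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    denom = np.sqrt(np.where(sds > 0, sds, 1.0))
    return (X - means) / denom, means, sds


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResults:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_pct: np.ndarray
    mean: np.ndarray


def pca(X, n_components: int | None = None) -> PCAResults:
    """Principal component analysis by SVD of the centered matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    evr = 100.0 * s ** 2 / np.sum(s ** 2)
    k = n_components or min(Xc.shape)
    return PCAResults(scores=u[:, :k] * s[:k], loadings=vt[:k],
                      explained_variance_pct=evr[:k], mean=X.mean(axis=0))


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS)

def _one_hot(labels, classes) -> np.ndarray:
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


class PLSDA:
    """Two-class PLS-DA model on a bucket (or any feature) matrix.

    Parameters
    ----------
    X : array-like or BucketMatrix
        Feature matrix, one row per sample.
    labels : sequence
        Class label per sample; exactly two classes, each with >= 2 samples.
    n_components : int
        Latent variables to extract.
    scale : {"pareto", None}
        Preprocessing applied to X (refit on the training part during
        cross-validation). ``None`` mean-centers only.
    """

    def __init__(self, X, labels, n_components: int = 2, scale: str | None = "pareto",
                 tol: float = 1e-12, max_iter: int = 500):
        if isinstance(X, BucketMatrix):
            X = X.to_array()
        self.X = np.asarray(X, dtype=float)
        self.labels = list(labels)
        self.classes_ = sorted(set(self.labels))
        if len(self.classes_) != 2:
            raise ValueError("PLS-DA here is two-class")
        for c in self.classes_:
            if self.labels.count(c) < 2:
                raise ValueError(f"class {c!r} needs at least 2 samples")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per row required")
        self.n_components = int(n_components)
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    # -- preprocessing -----------------------------------------------------
    def _preprocess(self, X):
        if self.scale == "pareto":
            Xs, mean, sd = pareto_scale(X)
            denom = np.sqrt(np.where(sd > 0, sd, 1.0))
        elif self.scale is None:
            mean = X.mean(axis=0)
            denom = np.ones(X.shape[1])
            Xs = X - mean
        else:
            raise ValueError(f"unknown scale {self.scale!r}")
        return Xs, mean, denom

    def fit(self) -> "PLSDAResults":
        Xc, x_mean, x_denom = self._preprocess(self.X)
        Y = _one_hot(self.labels, self.classes_)
        y_mean = Y.mean(axis=0)
        Yc = Y - y_mean
        tss = float(np.sum(Yc ** 2))

        n, p = Xc.shape
        A = min(self.n_components, n - 1, p)
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((Y.shape[1], A))
        T = np.zeros((n, A))
        U = np.zeros((n, A))
        ssy = np.zeros(A)

        Xr, Yr = Xc.copy(), Yc.copy()
        eps = np.finfo(float).eps
        n_eff = 0
        for a in range(A):
            if np.sum(Yr ** 2) <= 1e-14 * max(tss, 1.0):
                break  # Y residual exhausted; no further components
            u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                nw = np.linalg.norm(w)
                if nw <= eps:
                    raise RuntimeError(f"NIPALS degenerate weight at component {a + 1}")
                w /= nw
                t = Xr @ w
                tt = float(t @ t)
                if tt <= eps:
                    raise RuntimeError(f"NIPALS degenerate score at component {a + 1}")
                q = Yr.T @ t / tt
                u = Yr @ q / max(float(q @ q), eps)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * math.sqrt(tt):
                    break
                t_old = t
            else:
                raise RuntimeError(
                    f"NIPALS did not converge after {self.max_iter} iterations "
                    f"at component {a + 1}")
            pvec = Xr.T @ t / tt
            Xr = Xr - np.outer(t, pvec)
            Yr = Yr - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, pvec, q, t, u
            ssy[a] = tt * float(q @ q)
            n_eff = a + 1

        W, P, Q, T, U, ssy = (M[..., :n_eff] for M in (W, P, Q, T, U, ssy))
        r2y_per_comp = ssy / tss
        return PLSDAResults(
            model=self, weights=W, x_loadings=P, y_loadings=Q, x_scores=T,
            y_scores=U, ssy=ssy, r2y=float(r2y_per_comp.sum()),
            r2y_per_component=r2y_per_comp, x_mean=x_mean, x_denom=x_denom,
            y_mean=y_mean, classes=list(self.classes_),
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: latent structure, fit statistics and predictions."""

    model: PLSDA
    weights: np.ndarray          # p x A, unit-norm columns
    x_loadings: np.ndarray       # p x A
    y_loadings: np.ndarray       # 2 x A
    x_scores: np.ndarray         # n x A, orthogonal columns
    y_scores: np.ndarray
    ssy: np.ndarray              # Y sum of squares explained per component
    r2y: float                   # cumulative explained Y variance
    r2y_per_component: np.ndarray
    x_mean: np.ndarray
    x_denom: np.ndarray
    y_mean: np.ndarray
    classes: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def _regression_coef(self) -> np.ndarray:
        W, P, Q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def decision_values(self, X) -> np.ndarray:
        """Predicted (one-hot scale) Y values for new samples."""
        if isinstance(X, BucketMatrix):
            X = X.to_array()
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_denom
        return Xc @ self._regression_coef() + self.y_mean

    def predict(self, X) -> list:
        """Class prediction by argmax over predicted one-hot columns."""
        yhat = self.decision_values(X)
        return [self.classes[j] for j in np.argmax(yhat, axis=1)]

    def vip(self) -> np.ndarray:
        return vip(self)

    def cross_validate(self, n_segments: int = 7, groups=None) -> "ValidationReport":
        return plsda_cv(self.model.X, self.model.labels, n_segments=n_segments,
                        n_components=self.model.n_components,
                        scale=self.model.scale, groups=groups)

    def permutation_test(self, n_permutations: int = 100, seed: int = 0,
                         n_segments: int = 7) -> "PermutationResult":
        return permutation_test(self.model.X, self.model.labels,
                                n_permutations=n_permutations, seed=seed,
                                n_segments=n_segments,
                                n_components=self.model.n_components,
                                scale=self.model.scale)

    def summary(self) -> str:
        lines = [
            "PLS-DA results",
            "=" * 46,
            f"samples:            {self.model.X.shape[0]}",
            f"variables:          {self.model.X.shape[1]}",
            f"classes:            {self.classes[0]} vs {self.classes[1]}",
            f"components:         {self.n_components}",
            f"scaling:            {self.model.scale or 'center only'}",
            f"R2Y (cumulative):   {self.r2y:.3f}",
        ]
        for a, r in enumerate(self.r2y_per_component, start=1):
            lines.append(f"  component {a} R2Y:  {r:.3f}")
        return "\n".join(lines)


def plsda_fit(matrix, labels, n_components: int = 2) -> PLSDAResults:
    """Fit PLS-DA on an already-scaled matrix (centering only)."""
    return PLSDA(matrix, labels, n_components=n_components, scale=None).fit()


def vip(results: PLSDAResults) -> np.ndarray:
    """Variable Importance in the Projection.

    ``VIP_j = sqrt(p * sum_a ssy_a w_ja^2 / sum_a ssy_a)`` with unit-norm
    weight vectors, so the mean squared VIP equals one.
    """
    W, ssy = results.weights, results.ssy
    p = W.shape[0]
    w2 = W ** 2  # columns already unit norm
    return np.sqrt(p * (w2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Cross-validated performance of a PLS-DA configuration."""

    q2: float
    pct_correct: float
    fisher_p: float
    confusion: np.ndarray
    n_segments: int
    n_components: int

    def __post_init__(self):
        if not 0.0 <= self.pct_correct <= 100.0:
            raise ValueError("pct_correct out of range")
        if not 0.0 < self.fisher_p <= 1.0:
            raise ValueError("fisher_p out of range")

    def as_dict(self) -> dict:
        return {
            "q2": float(self.q2),
            "pct_correct": float(self.pct_correct),
            "fisher_p": float(self.fisher_p),
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "n_segments": int(self.n_segments),
            "n_components": int(self.n_components),
        }


def _segment_assignment(labels, n_segments: int, groups=None) -> np.ndarray:
    """Deterministic stratified segments: round-robin within each class.

    With ``groups`` (replicate ids), whole groups are assigned round-robin
    so replicates of one sample never straddle folds.
    """
    labels = list(labels)
    n = len(labels)
    seg = np.empty(n, dtype=int)
    if groups is None:
        for cls in sorted(set(labels)):
            idx = [i for i, lab in enumerate(labels) if lab == cls]
            for k, i in enumerate(idx):
                seg[i] = k % n_segments
    else:
        groups = list(groups)
        order = {}
        for cls in sorted(set(labels)):
            gseen = []
            for i, (lab, g) in enumerate(zip(labels, groups)):
                if lab == cls and g not in gseen:
                    gseen.append(g)
            for k, g in enumerate(gseen):
                order[g] = k % n_segments
        seg = np.array([order[g] for g in groups], dtype=int)
    return seg


def plsda_cv(X, labels, n_segments: int = 7, n_components: int = 2,
             scale: str | None = "pareto", groups=None) -> ValidationReport:
    """Segmented cross-validation of a PLS-DA configuration.

    Q2 = 1 - PRESS/TSS over held-out segments; class predictions are pooled
    across folds into a confusion matrix from which the % correct and the
    two-sided Fisher exact p-value are computed. ``n_segments`` equal to the
    sample count reproduces leave-one-out.
    """
    if isinstance(X, BucketMatrix):
        X = X.to_array()
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n_segments = min(n_segments, len(labels))
    classes = sorted(set(labels))
    seg = _segment_assignment(labels, n_segments, groups=groups)
    for s in range(n_segments):
        held = [labels[i] for i in np.nonzero(seg == s)[0]]
        for cls in classes:
            if held.count(cls) == labels.count(cls):
                raise ValueError(f"segment {s} contains the entire class {cls!r}")

    Y = _one_hot(labels, classes)
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    press = 0.0
    predicted = [None] * len(labels)
    for s in range(n_segments):
        test = np.nonzero(seg == s)[0]
        train = np.nonzero(seg != s)[0]
        res = PLSDA(X[train], [labels[i] for i in train],
                    n_components=n_components, scale=scale).fit()
        yhat = res.decision_values(X[test])
        press += float(np.sum((Y[test] - yhat) ** 2))
        for i, lab in zip(test, res.predict(X[test])):
            predicted[i] = lab

    q2 = 1.0 - press / tss
    correct = sum(p == t for p, t in zip(predicted, labels))
    pct_correct = 100.0 * correct / len(labels)
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(labels, predicted):
        confusion[classes.index(t), classes.index(p)] += 1
    try:
        fisher_p = fisher_exact_2x2(confusion)
    except ValueError:  # a zero margin: association untestable
        fisher_p = 1.0
    return ValidationReport(q2=q2, pct_correct=pct_correct, fisher_p=fisher_p,
                            confusion=confusion, n_segments=n_segments,
                            n_components=n_components)


@dataclass
class PermutationResult:
    """Label-permutation validation of a PLS-DA model.

    ``r2_intercept``/``q2_intercept`` are the intercepts at zero label
    correlation of the regression of permuted R2Y and Q2 on the absolute
    correlation with the true labels (the original model is included at
    correlation one). A valid model has all permuted values below the
    original and a negative Q2 intercept.
    """

    r2y_original: float
    q2_original: float
    r2y_permuted: np.ndarray
    q2_permuted: np.ndarray
    correlations: np.ndarray
    r2_intercept: float
    q2_intercept: float
    n_permutations: int

    @property
    def valid(self) -> bool:
        return (bool(np.all(self.r2y_permuted < self.r2y_original))
                and bool(np.all(self.q2_permuted < self.q2_original))
                and self.q2_intercept < 0)

    def as_dict(self) -> dict:
        return {
            "r2y_original": float(self.r2y_original),
            "q2_original": float(self.q2_original),
            "r2_intercept": float(self.r2_intercept),
            "q2_intercept": float(self.q2_intercept),
            "n_permutations": int(self.n_permutations),
            "valid": self.valid,
        }


def permutation_test(X, labels, n_permutations: int = 100, seed: int = 0,
                     n_segments: int = 7, n_components: int = 2,
                     scale: str | None = "pareto") -> PermutationResult:
    """Refit model + cross-validation under permuted class labels."""
    if isinstance(X, BucketMatrix):
        X = X.to_array()
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    classes = sorted(set(labels))
    y_num = np.array([classes.index(lab) for lab in labels], dtype=float)

    res0 = PLSDA(X, labels, n_components=n_components, scale=scale).fit()
    cv0 = plsda_cv(X, labels, n_segments=n_segments, n_components=n_components,
                   scale=scale)

    rng = np.random.default_rng(seed)
    r2s, q2s, corrs = [], [], []
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        plab = [labels[i] for i in perm]
        pres = PLSDA(X, plab, n_components=n_components, scale=scale).fit()
        pcv = plsda_cv(X, plab, n_segments=n_segments, n_components=n_components,
                       scale=scale)
        r2s.append(pres.r2y)
        q2s.append(pcv.q2)
        corrs.append(abs(float(np.corrcoef(y_num, y_num[perm])[0, 1])))

    xs = np.concatenate([corrs, [1.0]])
    r2_line = np.polyfit(xs, np.concatenate([r2s, [res0.r2y]]), 1)
    q2_line = np.polyfit(xs, np.concatenate([q2s, [cv0.q2]]), 1)
    return PermutationResult(
        r2y_original=res0.r2y, q2_original=cv0.q2,
        r2y_permuted=np.array(r2s), q2_permuted=np.array(q2s),
        correlations=np.array(corrs),
        r2_intercept=float(r2_line[1]), q2_intercept=float(q2_line[1]),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# univariate / auxiliary statistics

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 contingency table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (the standard two-sided convention). Perfect separation of 14 vs 16
    samples gives 1/C(30,14) ~ 6.9e-9.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise ValueError("table margins must be positive")
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def hotelling_outliers(scores, alpha: float = 0.05) -> np.ndarray:
    """Flag samples outside the 100(1-alpha)% Hotelling-T2 limit.

    ``T2_i = z_i' S^-1 z_i`` on centered scores with sample covariance S;
    the limit is ``A (n-1) / (n-A) * F_{1-alpha}(A, n-A)``. All-identical
    scores flag nothing; a genuinely singular covariance is an error.
    """
    Z = np.atleast_2d(np.asarray(scores, dtype=float))
    if Z.ndim != 2:
        raise ValueError("scores must be 2D (samples x components)")
    n, A = Z.shape
    if n < 3 or n <= A:
        raise ValueError("need at least 3 samples and more samples than components")
    Zc = Z - Z.mean(axis=0)
    if np.allclose(Zc, 0.0):
        return np.zeros(n, dtype=bool)
    S = np.cov(Zc, rowvar=False, ddof=1).reshape(A, A)
    if np.linalg.matrix_rank(S) < A:
        raise ValueError("singular score covariance")
    t2 = np.einsum("ij,ij->i", Zc @ np.linalg.inv(S), Zc)
    limit = A * (n - 1) / (n - A) * stats.f.ppf(1.0 - alpha, A, n - A)
    return t2 > limit


def marker_ttest(values_group1, values_group2, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test on a marker (Welch by default).

    Zero-variance identical groups return ``(0.0, 1.0)``.
    """
    g1 = np.asarray(list(values_group1), dtype=float)
    g2 = np.asarray(list(values_group2), dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need at least 2 values per group")
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    if np.isnan(t):  # degenerate: both groups constant
        return 0.0, 1.0
    return float(t), float(p)
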