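"""Linear discriminant analysis of Procrustes shape.

Procrustes coordinates occupy a degenerate subspace of the 2k landmark
coordinates (four dimensions — two translations, rotation, and size —
are removed by superimposition), so discriminant computations run in a
principal-component basis retaining every numerically nonzero direction.
Classification uses Gaussian discriminant scores with a shared
(pooled within-group) covariance; ordination axes solve the generalized
eigenproblem of between- versus within-group scatter, scaled so LD
scores have unit pooled within-group variance (the canonical-variate
convention).

Group order everywhere follows first appearance in the label vector,
matching the dataset's declared taxon order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin

from .procrustes import GPAResult

__all__ = [
    "ProcrustesLDA",
    "ConfusionMatrix",
    "HullSet",
    "fit_lda",
    "loocv",
    "summarize_confusion",
    "convex_hulls",
    "rank_reduce",
]


def _flatten(X) -> np.ndarray:
    if isinstance(X, GPAResult):
        return X.flat()
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2:
        raise ValueError("expected (n, 2k) or (n, k, 2) shape data")
    return arr


def _ordered_classes(y: np.ndarray) -> np.ndarray:
    seen: dict = {}
    for v in y:
        seen.setdefault(v, None)
    return np.array(list(seen), dtype=object)


def rank_reduce(X: np.ndarray, rel_tol: float = 1e-8):
    """Principal-component reduction to the data's numerical rank.

    Returns ``(scores, basis, mean)`` with ``scores = (X - mean) @ basis``.
    Directions with singular value ≤ ``rel_tol`` times the largest are
    dropped; on clean Procrustes data this removes exactly the four
    superimposition-degenerate dimensions.
    """
    mean = X.mean(axis=0)
    xc = X - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > rel_tol * s[0]
    basis = vt[keep].T
    return xc @ basis, basis, mean


class ProcrustesLDA(ClassifierMixin, BaseEstimator):
    """Shared-covariance linear discriminant classifier for shape data.

    Parameters
    ----------
    priors : {"proportional", "equal"} or array of g probabilities
        ``"proportional"`` (default) uses observed group frequencies.
    rank_tol : float
        Relative singular-value threshold of the principal-component
        reduction.
    ridge : float
        Relative ridge added to the pooled covariance diagonal if it is
        numerically singular (with a warning).

    Attributes
    ----------
    classes_ : (g,) array — group labels in first-appearance order.
    basis_ : (2k, r) orthonormal reduction.
    mean_ : (2k,) overall mean removed before reduction.
    group_means_ : (g, r) group means in the reduced basis.
    pooled_covariance_ : (r, r) within-group covariance (denominator n−g).
    scalings_ : (r, a) discriminant axes, aᵀ Σ_pooled a = I.
    explained_variance_ratio_ : (a,) eigenvalue proportions (sum 1).
    priors_ : (g,) class priors.
    """

    def __init__(self, priors="proportional", rank_tol: float = 1e-8, ridge: float = 1e-8):
        self.priors = priors
        self.rank_tol = rank_tol
        self.ridge = ridge

    def fit(self, X, y) -> "ProcrustesLDA":
        X = _flatten(X)
        y = np.asarray(y, dtype=object).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = _ordered_classes(y)
        g = len(classes)
        n = X.shape[0]
        if g < 2:
            raise ValueError("need at least 2 groups")
        if n <= g:
            raise ValueError("need more specimens than groups")
        counts = np.array([(y == c).sum() for c in classes])
        if counts.min() < 2:
            bad = classes[counts.argmin()]
            raise ValueError(f"group {bad!r} has fewer than 2 specimens")

        z, basis, mean = rank_reduce(X, self.rank_tol)
        r = z.shape[1]
        means = np.vstack([z[y == c].mean(axis=0) for c in classes])

        w = np.zeros((r, r))
        for c, m in zip(classes, means):
            d = z[y == c] - m
            w += d.T @ d
        grand = (counts[:, None] * means).sum(axis=0) / n
        dm = means - grand
        b = (counts[:, None] * dm).T @ dm

        # the within-group covariance must be positive definite both for the
        # eigenproblem and for classification; if a fold or a degenerate
        # draw leaves it rank-deficient, escalate a relative ridge
        cov = (w + w.T) / (2.0 * (n - g))
        base = float(np.mean(np.diag(cov))) or 1.0
        for bump in (0.0, self.ridge, self.ridge * 1e4, self.ridge * 1e8):
            try:
                trial = cov + bump * base * np.eye(r)
                cov_solve = scipy.linalg.cho_factor(trial)
                evals, evecs = scipy.linalg.eigh(b, trial * (n - g))  # vᵀ W v = I
            except scipy.linalg.LinAlgError:
                continue
            if bump:
                warnings.warn(
                    f"singular pooled covariance; adding ridge {bump * base:.3e} to the diagonal"
                )
            cov = trial
            break
        else:
            raise scipy.linalg.LinAlgError("pooled covariance could not be regularized")
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, r)
        evals = np.clip(evals[order][:n_axes], 0.0, None)
        axes = evecs[:, order][:, :n_axes] * np.sqrt(n - g)  # aᵀ Σ a = I
        total = evals.sum()
        ratio = evals / total if total > 0 else np.full(n_axes, 1.0 / n_axes)

        self.classes_ = classes
        self.counts_ = counts
        self.basis_ = basis
        self.mean_ = mean
        self.group_means_ = means
        self.pooled_covariance_ = cov
        self.scalings_ = axes
        self.eigenvalues_ = evals
        self.explained_variance_ratio_ = ratio
        self.priors_ = self._resolve_priors(counts, n)
        self._cov_solve = cov_solve
        return self

    def _resolve_priors(self, counts: np.ndarray, n: int) -> np.ndarray:
        if isinstance(self.priors, str):
            if self.priors == "proportional":
                return counts / n
            if self.priors == "equal":
                return np.full(len(counts), 1.0 / len(counts))
            raise ValueError(f"unknown priors policy {self.priors!r}")
        p = np.asarray(self.priors, dtype=float)
        if p.shape != (len(counts),) or not np.isclose(p.sum(), 1.0):
            raise ValueError("priors must be g probabilities summing to 1")
        return p

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise ValueError("ProcrustesLDA is not fitted")

    def _reduce(self, X) -> np.ndarray:
        return (_flatten(X) - self.mean_) @ self.basis_

    def decision_function(self, X) -> np.ndarray:
        """Gaussian discriminant scores (log posterior up to a constant)."""
        self._check_fitted()
        z = self._reduce(X)
        sim = scipy.linalg.cho_solve(self._cov_solve, self.group_means_.T)  # (r, g)
        lin = z @ sim
        const = -0.5 * np.sum(self.group_means_ * sim.T, axis=1) + np.log(self.priors_)
        return lin + const

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        best = scores.max(axis=1, keepdims=True)
        ties = (np.isclose(scores, best, rtol=0.0, atol=1e-12)).sum(axis=1) > 1
        if ties.any():
            warnings.warn(
                f"{int(ties.sum())} tied classification score(s); "
                "assigned to the lowest group index"
            )
        return self.classes_[scores.argmax(axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    def transform(self, X) -> np.ndarray:
        """Project onto discriminant (canonical-variate) axes."""
        self._check_fitted()
        grand = (self.counts_[:, None] * self.group_means_).sum(axis=0) / self.counts_.sum()
        return (self._reduce(X) - grand) @ self.scalings_


def fit_lda(gpa: GPAResult | np.ndarray, groups: Sequence, priors="proportional", **kw) -> ProcrustesLDA:
    """Fit a shared-covariance discriminant model on Procrustes shapes."""
    return ProcrustesLDA(priors=priors, **kw).fit(gpa, groups)


@dataclass
class ConfusionMatrix:
    """Cross-classification counts (rows = true taxon, columns = assigned)."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be square and match labels")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if c.sum() == 0:
            raise ValueError("confusion matrix has no observations")
        self.counts = c

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Diagonal fraction per row; NaN for an empty row."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / totals
        return np.where(totals > 0, acc, np.nan)

    def rate(self, true_label: str, assigned_label: str) -> float:
        i = self.labels.index(true_label)
        j = self.labels.index(assigned_label)
        rt = self.row_totals[i]
        return float(self.counts[i, j] / rt) if rt else float("nan")

    @staticmethod
    def percent(fraction: float, decimals: int = 1) -> float:
        """Percentage rounded half-up to the given decimals (table style)."""
        if np.isnan(fraction):
            return float("nan")
        q = Decimal(1).scaleb(-decimals)
        return float(Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP))

    def to_frame(self, percentages: bool = True):
        """Table-style layout: 'xx.x% (n/m)' cells (or raw counts)."""
        import pandas as pd

        if not percentages:
            return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        cells = []
        for i, row in enumerate(self.counts):
            rt = self.row_totals[i]
            cells.append(
                [
                    f"{self.percent(c / rt):.1f}% ({c}/{rt})" if rt else "—"
                    for c in row
                ]
            )
        return pd.DataFrame(cells, index=self.labels, columns=self.labels)


def summarize_confusion(counts, labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """Wrap raw cross-classification counts with accuracy summaries."""
    c = np.asarray(counts)
    if labels is None:
        labels = [f"group{i}" for i in range(c.shape[0])]
    return ConfusionMatrix(list(labels), c.astype(int))


def loocv(
    X,
    groups: Sequence,
    priors="proportional",
    rank_tol: float = 1e-8,
    refit_gpa: bool = False,
    raw_dataset=None,
    gpa_kwargs: dict | None = None,
) -> ConfusionMatrix:
    """Jackknife leave-one-out cross-validated classification.

    Each specimen is withheld, the discriminant model is refit on the
    rest, and the specimen is assigned by highest posterior.  By default
    superimposition is *not* recomputed per fold (the standard jackknife
    on fixed Procrustes coordinates); ``refit_gpa=True`` re-runs GPA on
    each training fold and superimposes the held-out specimen onto that
    fold's consensus (requires ``raw_dataset`` with raw coordinates).
    """
    y = np.asarray(groups, dtype=object).ravel()
    classes = _ordered_classes(y)
    counts_per = {c: (y == c).sum() for c in classes}
    small = [c for c, m in counts_per.items() if m < 2]
    if small:
        raise ValueError(f"cannot leave out from group(s) of size 1: {small}")

    if refit_gpa:
        from .procrustes import GeneralizedProcrustes

        if raw_dataset is None:
            raise ValueError("refit_gpa=True requires raw_dataset")
        raw = GeneralizedProcrustes._as_array(raw_dataset)
        gkw = gpa_kwargs or {}
    else:
        flat = _flatten(X)

    n = len(y)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if refit_gpa:
            est = GeneralizedProcrustes(**gkw).fit(raw[mask])
            train = est.aligned_.reshape(mask.sum(), -1)
            test = est.transform(raw[i : i + 1]).reshape(1, -1)
        else:
            train = flat[mask]
            test = flat[i : i + 1]
        model = ProcrustesLDA(priors=priors, rank_tol=rank_tol).fit(train, y[mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = model.predict(test)[0]
        cm[idx[y[i]], idx[pred]] += 1
    return ConfusionMatrix(list(classes), cm)


@dataclass
class HullSet:
    """Per-group convex-hull vertices in an ordination plane (CCW order)."""

    hulls: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.hulls[name]

    def to_frame(self):
        import pandas as pd

        rows = []
        for g, verts in self.hulls.items():
            for i, (x, y) in enumerate(verts):
                rows.append({"group": g, "vertex": i, "x": x, "y": y})
        return pd.DataFrame(rows)


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain convex hull; CCW vertices.

    Degenerate inputs collapse gracefully: one unique point yields a
    1-vertex "hull", collinear points yield the two extremes.
    """
    pts = np.unique(points, axis=0)  # lexicographic sort + dedup
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 2:  # all points collinear → keep the two extremes
        hull = [pts[0], pts[-1]]
    return np.array(hull)


def convex_hulls(scores: np.ndarray, groups: Sequence) -> HullSet:
    """Convex-hull envelope of each group's points in a 2-D score plane."""
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    y = np.asarray(groups, dtype=object).ravel()
    if len(y) != len(pts):
        raise ValueError("scores and groups length mismatch")
    out: dict[str, np.ndarray] = {}
    for g in _ordered_classes(y):
        sub = pts[y == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no points")
        out[g] = _monotone_chain(sub)
    return HullSet(out)
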