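"""Pairwise Mahalanobis distances between group mean shapes, with
permutation significance, as produced by canonical variate analysis.

Distances are computed in the same principal-component reduction used by
the discriminant module, with the pooled within-group covariance over
*all* groups as the metric, so distances and classifications live in one
space.  The permutation null for each pair shuffles specimen-to-group
labels within that pair only and recomputes the distance (including the
pair's contribution to the pooled covariance); p-values use the add-one
convention and receive no multiple-testing correction by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .discriminant import _flatten, _ordered_classes, rank_reduce
from .procrustes import GPAResult

__all__ = ["DistanceMatrix", "mahalanobis_matrix", "mahalanobis_distances"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise group distances with permutation p-values."""

    labels: list[str]
    distances: np.ndarray
    p_values: np.ndarray | None
    n_permutations: int
    seed: int | None

    def distance(self, a: str, b: str) -> float:
        return float(self.distances[self.labels.index(a), self.labels.index(b)])

    def p_value(self, a: str, b: str) -> float:
        if self.p_values is None:
            raise ValueError("no permutation test was run")
        return float(self.p_values[self.labels.index(a), self.labels.index(b)])

    def bonferroni(self) -> np.ndarray:
        """Bonferroni-adjusted p-values (off-diagonal), capped at 1."""
        g = len(self.labels)
        m = g * (g - 1) // 2
        adj = np.minimum(self.p_values * m, 1.0)
        np.fill_diagonal(adj, 0.0)
        return adj

    def to_frame(self):
        """Distances in the lower triangle, p-values in the upper."""
        import pandas as pd

        g = len(self.labels)
        out = np.full((g, g), np.nan)
        il = np.tril_indices(g, -1)
        iu = np.triu_indices(g, 1)
        out[il] = self.distances[il]
        if self.p_values is not None:
            out[iu] = self.p_values[iu]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def _pooled_scatter(z: np.ndarray, y: np.ndarray, classes: np.ndarray):
    means = {}
    w = np.zeros((z.shape[1], z.shape[1]))
    for c in classes:
        sub = z[y == c]
        m = sub.mean(axis=0)
        means[c] = m
        d = sub - m
        w += d.T @ d
    return means, w


def mahalanobis_distances(
    z: np.ndarray, groups: Sequence, ddof: str = "n-g", ridge: float = 1e-8
) -> DistanceMatrix:
    """Pairwise Mahalanobis distances on a plain (n, d) feature matrix.

    D(i,j) = sqrt((μᵢ−μⱼ)ᵀ S⁻¹ (μᵢ−μⱼ)) with S the pooled within-group
    covariance (denominator n−g, or n with ``ddof="n"``).  No
    permutation test; see :func:`mahalanobis_matrix` for that.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(groups, dtype=object).ravel()
    if len(y) != z.shape[0]:
        raise ValueError("z and groups length mismatch")
    classes = _ordered_classes(y)
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 specimens")
    n, g = z.shape[0], len(classes)
    denom = n - g if ddof == "n-g" else n
    means, w = _pooled_scatter(z, y, classes)
    s = w / denom
    factor = _spd_factor(s, ridge)
    d = np.zeros((g, g))
    for i, j in itertools.combinations(range(g), 2):
        diff = means[classes[i]] - means[classes[j]]
        d[i, j] = d[j, i] = np.sqrt(diff @ scipy.linalg.cho_solve(factor, diff))
    return DistanceMatrix(list(classes), d, None, 0, None)


def _spd_factor(s: np.ndarray, ridge: float):
    s = (s + s.T) / 2.0
    try:
        return scipy.linalg.cho_factor(s)
    except scipy.linalg.LinAlgError:
        bump = ridge * float(np.mean(np.diag(s)))
        if bump <= 0.0:
            bump = ridge
        warnings.warn(f"singular pooled covariance; adding ridge {bump:.3e}")
        return scipy.linalg.cho_factor(s + bump * np.eye(s.shape[0]))


def mahalanobis_matrix(
    X,
    groups: Sequence,
    n_permutations: int = 10_000,
    seed: int = 0,
    ddof: str = "n-g",
    rank_tol: float = 1e-8,
    ridge: float = 1e-8,
    mode: str = "pairwise",
) -> DistanceMatrix:
    """Mahalanobis distance matrix between group mean shapes + permutation p.

    ``X`` may be a GPAResult, an (n, k, 2) stack, or an (n, d) matrix.
    The permutation test (``mode="pairwise"``, the default) shuffles the
    two groups' labels jointly for each pair; ``mode="global"`` shuffles
    all labels at once and re-reads every pair from each shuffle.
    p = (exceedances + 1) / (n_permutations + 1).
    """
    if ddof not in ("n-g", "n"):
        raise ValueError("ddof must be 'n-g' or 'n'")
    flat = _flatten(X)
    z, _, _ = rank_reduce(flat, rank_tol)
    y = np.asarray(groups, dtype=object).ravel()
    if len(y) != z.shape[0]:
        raise ValueError("X and groups length mismatch")
    classes = _ordered_classes(y)
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, m in counts.items() if m < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 specimens: {small}")
    n, g, r = z.shape[0], len(classes), z.shape[1]
    denom = n - g if ddof == "n-g" else n

    means, w_total = _pooled_scatter(z, y, classes)
    s = w_total / denom
    factor = _spd_factor(s, ridge)
    d_obs = np.zeros((g, g))
    for i, j in itertools.combinations(range(g), 2):
        diff = means[classes[i]] - means[classes[j]]
        d_obs[i, j] = d_obs[j, i] = np.sqrt(diff @ scipy.linalg.cho_solve(factor, diff))

    if n_permutations <= 0:
        return DistanceMatrix(list(classes), d_obs, None, 0, seed)

    rng = np.random.default_rng(seed)
    pvals = np.zeros((g, g))

    if mode == "global":
        exceed = np.zeros((g, g))
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            mp, wp = _pooled_scatter(z, yp, classes)
            fp = _spd_factor(wp / denom, ridge)
            for i, j in itertools.combinations(range(g), 2):
                diff = mp[classes[i]] - mp[classes[j]]
                dp = np.sqrt(diff @ scipy.linalg.cho_solve(fp, diff))
                if dp >= d_obs[i, j]:
                    exceed[i, j] += 1
        for i, j in itertools.combinations(range(g), 2):
            pvals[i, j] = pvals[j, i] = (exceed[i, j] + 1) / (n_permutations + 1)
        return DistanceMatrix(list(classes), d_obs, pvals, n_permutations, seed)

    if mode != "pairwise":
        raise ValueError("mode must be 'pairwise' or 'global'")

    # per-pair permutation: only the pair's within-scatter and means move;
    # every other group's contribution to the pooled scatter is fixed.
    for i, j in itertools.combinations(range(g), 2):
        ci, cj = classes[i], classes[j]
        zi, zj = z[y == ci], z[y == cj]
        pair = np.vstack([zi, zj])
        n1 = len(zi)
        npair = len(pair)
        t_pair = pair.T @ pair
        wi = (zi - means[ci]).T @ (zi - means[ci])
        wj = (zj - means[cj]).T @ (zj - means[cj])
        w_rest = w_total - wi - wj
        pair_sum = pair.sum(axis=0)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(npair)
            m1 = pair[perm[:n1]].mean(axis=0)
            m2 = (pair_sum - m1 * n1) / (npair - n1)
            w_pair = t_pair - n1 * np.outer(m1, m1) - (npair - n1) * np.outer(m2, m2)
            fp = _spd_factor((w_rest + w_pair) / denom, ridge)
            diff = m1 - m2
            dp = np.sqrt(max(0.0, diff @ scipy.linalg.cho_solve(fp, diff)))
            if dp >= d_obs[i, j]:
                exceed += 1
        pvals[i, j] = pvals[j, i] = (exceed + 1) / (n_permutations + 1)

    return DistanceMatrix(list(classes), d_obs, pvals, n_permutations, seed)
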