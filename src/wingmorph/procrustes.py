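"""Generalized Procrustes analysis (GPA) for 2-D landmark configurations.

GPA removes the nuisance parameters of digitized landmark data —
position, scale and orientation — leaving Procrustes shape coordinates,
per-specimen centroid sizes, and a consensus (mean) shape.  The default
is *partial* Procrustes superimposition (every configuration fixed at
unit centroid size, rotation optimized), the dominant convention in
geometric morphometrics; full-Procrustes scaling is available via
``scale="full"``.  Reflections are never permitted in alignment: all
configurations are assumed digitized with a consistent chirality (e.g.
right wings only).

Aligned coordinates are, by default, orthogonally projected onto the
linear tangent space at the consensus, so ordinary multivariate
statistics apply downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tps import LandmarkDataset

__all__ = [
    "GPAResult",
    "MeanShapeComparison",
    "GeneralizedProcrustes",
    "centroid_size",
    "optimal_rotation",
    "procrustes_distance",
    "gpa",
    "mean_shapes",
]


def centroid_size(landmarks: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Invariant under rotation and translation; scales linearly under
    uniform scaling.  A fully degenerate configuration (all landmarks
    coincident) returns 0.0 with a warning rather than raising.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.ndim != 2 or lm.shape[1] != 2 or lm.shape[0] < 3:
        raise ValueError("landmarks must be a (k>=3, 2) array")
    if not np.all(np.isfinite(lm)):
        raise ValueError("landmark coordinates must be finite")
    cs = float(np.sqrt(((lm - lm.mean(axis=0)) ** 2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincide (CS = 0)")
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2×2 rotation R minimizing ||source @ R.T - target||_F.

    Both shapes must be centered.  Computed from the SVD of the 2×2
    cross-covariance with determinant sign correction, so a reflection is
    never returned even when it would fit better.  A zero cross-covariance
    yields the identity with a warning.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("source and target must be (k, 2) arrays of equal shape")
    m = s.T @ t  # maximize tr(R m)
    if not np.any(m):
        warnings.warn("zero cross-covariance between shapes; returning identity rotation")
        return np.eye(2)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, d]) @ u.T


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def _unit(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x)


def procrustes_distance(a: np.ndarray, b: np.ndarray, kind: str = "full") -> float:
    """Procrustes distance between two configurations.

    ``kind="full"`` is the full Procrustes distance
    sqrt(1 − ρ²) with ρ the maximal shape correlation over proper
    rotations and scale; ``kind="partial"`` is the residual norm between
    the unit-size shapes after optimal rotation only.
    """
    za = _unit(_center(np.asarray(a, dtype=float)))
    zb = _unit(_center(np.asarray(b, dtype=float)))
    m = za.T @ zb
    sv = np.linalg.svd(m, compute_uv=False)
    rho = sv[0] + np.sign(np.linalg.det(m)) * sv[1]
    rho = min(rho, 1.0)
    if kind == "full":
        return float(np.sqrt(max(0.0, 1.0 - rho**2)))
    if kind == "partial":
        return float(np.sqrt(max(0.0, 2.0 - 2.0 * rho)))
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class GPAResult:
    """Superimposition output.

    Attributes
    ----------
    aligned : (n, k, 2) ndarray
        Procrustes coordinates (dimensionless, unit-centroid-size scale).
    centroid_sizes : (n,) ndarray
        Pre-scaling centroid sizes in the input's coordinate units.
    consensus : (k, 2) ndarray
        Mean shape, unit centroid size, principal axis along +x.
    iterations : int
    converged : bool
    projection : bool
        Whether tangent-space projection at the consensus was applied.
    scale : str
        ``"unit"`` (partial Procrustes) or ``"full"``.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    projection: bool
    scale: str = "unit"

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned shapes flattened to (n, 2k), row order x1,y1,…,xk,yk."""
        return self.aligned.reshape(self.n, -1)

    def procrustes_variance(self) -> float:
        """Mean squared deviation of aligned shapes from the consensus."""
        dev = self.aligned - self.consensus
        return float((dev**2).sum() / self.n)


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized Procrustes superimposition as a transformer.

    ``fit`` iteratively aligns a set of configurations: each is centered
    and scaled to unit centroid size, then rotations onto the running
    consensus and consensus re-estimation alternate until the consensus
    moves less than ``tol`` (Procrustes distance) or ``max_iter`` is
    reached.  The consensus's rotational gauge is fixed by aligning its
    principal axis with +x (orientation disambiguated by third-moment
    sign), so results are reproducible across runs and input orderings.

    ``transform`` superimposes configurations (including unseen ones)
    onto the fitted consensus.

    Parameters
    ----------
    tol : float
        Convergence threshold on the consensus change between iterations.
    max_iter : int
        Iteration budget; non-convergence is recorded, not raised.
    project : bool
        Orthogonally project aligned shapes onto the tangent space at the
        consensus (on by default).
    scale : {"unit", "full"}
        ``"unit"``: partial Procrustes, every shape kept at unit centroid
        size.  ``"full"``: per-shape scale optimized against the
        consensus in each iteration.

    Attributes
    ----------
    consensus_ : (k, 2) ndarray
    aligned_ : (n, k, 2) ndarray
    centroid_sizes_ : (n,) ndarray
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        tol: float = 1e-10,
        max_iter: int = 100,
        project: bool = True,
        scale: str = "unit",
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.project = project
        self.scale = scale

    # -- helpers -------------------------------------------------------

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, LandmarkDataset):
            X = X.coords()
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) coordinate array or LandmarkDataset")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        return arr

    @staticmethod
    def _gauge_rotation(consensus: np.ndarray) -> np.ndarray:
        """Proper rotation putting the consensus's principal axis along +x."""
        cov = consensus.T @ consensus
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, np.argmax(evals)]
        r = np.array([[major[0], major[1]], [-major[1], major[0]]])  # rotates major → +x
        rotated = consensus @ r.T
        if np.sum(rotated[:, 0] ** 3) < 0:  # deterministic 180° disambiguation
            r = -r
        return r

    def fit(self, X, y=None) -> "GeneralizedProcrustes":
        if self.scale not in ("unit", "full"):
            raise ValueError("scale must be 'unit' or 'full'")
        arr = self._as_array(X)
        n = arr.shape[0]
        if n < 2:
            raise ValueError("GPA requires at least 2 configurations")

        sizes = np.array([centroid_size(c) for c in arr])
        if np.any(sizes == 0):
            raise ValueError("cannot superimpose a fully degenerate configuration")
        shapes = np.array([_center(c) / s for c, s in zip(arr, sizes)])

        consensus = shapes[0].copy()
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                r = optimal_rotation(shapes[i], consensus)
                shapes[i] = shapes[i] @ r.T
                if self.scale == "full":
                    beta = float(np.sum(shapes[i] * consensus))
                    shapes[i] = shapes[i] * beta
            new_consensus = shapes.mean(axis=0)
            new_consensus = new_consensus / centroid_size(new_consensus)
            shift = procrustes_distance(consensus, new_consensus, kind="partial")
            consensus = new_consensus
            if shift < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"GPA did not converge within {self.max_iter} iterations")

        g = self._gauge_rotation(consensus)
        consensus = consensus @ g.T
        shapes = shapes @ g.T
        # one final rotation pass so every shape is optimally posed w.r.t.
        # the gauge-fixed consensus
        for i in range(n):
            r = optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ r.T

        if self.project:
            shapes = self._project(shapes, consensus)

        self.consensus_ = consensus
        self.aligned_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    @staticmethod
    def _project(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
        """Orthogonal projection onto the tangent hyperplane at the consensus."""
        c = consensus.reshape(-1)
        c = c / np.linalg.norm(c)
        flat = shapes.reshape(shapes.shape[0], -1)
        flat = flat - np.outer(flat @ c - 1.0, c)
        return flat.reshape(shapes.shape)

    def transform(self, X) -> np.ndarray:
        """Superimpose configurations onto the fitted consensus."""
        if not hasattr(self, "consensus_"):
            raise ValueError("GeneralizedProcrustes is not fitted")
        arr = self._as_array(X)
        out = np.empty_like(arr)
        for i, c in enumerate(arr):
            s = _center(c) / centroid_size(c)
            r = optimal_rotation(s, self.consensus_)
            s = s @ r.T
            if self.scale == "full":
                s = s * float(np.sum(s * self.consensus_))
            out[i] = s
        if self.project:
            out = self._project(out, self.consensus_)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).aligned_

    def result_(self) -> GPAResult:
        if not hasattr(self, "consensus_"):
            raise ValueError("GeneralizedProcrustes is not fitted")
        return GPAResult(
            aligned=self.aligned_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            iterations=self.n_iter_,
            converged=self.converged_,
            projection=self.project,
            scale=self.scale,
        )


def gpa(
    dataset,
    tol: float = 1e-10,
    max_iter: int = 100,
    project: bool = True,
    scale: str = "unit",
) -> GPAResult:
    """Run generalized Procrustes analysis on a dataset or (n, k, 2) array."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter, project=project, scale=scale)
    est.fit(dataset)
    return est.result_()


@dataclass
class MeanShapeComparison:
    """Per-group mean Procrustes shapes and pairwise landmark displacements."""

    group_names: list[str]
    group_means: dict[str, np.ndarray]  # name -> (k, 2)
    per_landmark_displacement: dict[tuple[str, str], np.ndarray]  # pair -> (k,)

    def displacement(self, a: str, b: str) -> np.ndarray:
        if a == b:
            return np.zeros(next(iter(self.group_means.values())).shape[0])
        key = (a, b) if (a, b) in self.per_landmark_displacement else (b, a)
        return self.per_landmark_displacement[key]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (a, b), disp in self.per_landmark_displacement.items():
            for lm, d in enumerate(disp, start=1):
                rows.append({"group_a": a, "group_b": b, "landmark": lm, "displacement": d})
        return pd.DataFrame(rows)


def mean_shapes(result: GPAResult, groups: Sequence[str]) -> MeanShapeComparison:
    """Group mean shapes and pairwise per-landmark displacement magnitudes.

    ``groups`` is the per-specimen taxon label sequence, aligned with
    ``result.aligned``.  Group order follows first appearance.
    """
    labels = np.asarray(groups, dtype=object)
    if labels.shape[0] != result.n:
        raise ValueError("groups length must match the number of aligned specimens")
    names: list[str] = []
    for g in labels:
        if g not in names:
            names.append(g)
    means: dict[str, np.ndarray] = {}
    for g in names:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} has no specimens")
        means[g] = result.aligned[mask].mean(axis=0)
    disp: dict[tuple[str, str], np.ndarray] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            disp[(a, b)] = np.linalg.norm(means[a] - means[b], axis=1)
    return MeanShapeComparison(names, means, disp)
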