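"""Centroid-size group statistics and the shape-on-size allometry test.

Wing size is summarized by centroid size (CS).  Group CS means are
compared with a one-way fixed-effects ANOVA plus pairwise t-tests using
the pooled residual variance (Bonferroni-adjusted, capped at 1), the
convention of the common agricultural-statistics implementations.

Allometry — the dependence of shape on size — is quantified by the
fraction of total Procrustes shape variance explained by an ordinary
least-squares regression of the flattened Procrustes coordinates on log
CS, with significance from a permutation test that shuffles sizes across
specimens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .procrustes import GPAResult

__all__ = ["SizeAnovaResult", "AllometryResult", "size_anova", "allometry_test"]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass
class SizeAnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    pairwise: list[PairwiseComparison]

    def pairwise_p(self, a: str, b: str) -> float:
        for c in self.pairwise:
            if {c.group_a, c.group_b} == {a, b}:
                return c.p_adjusted
        raise KeyError(f"no comparison for pair ({a}, {b})")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "t": c.t,
                    "df": c.df,
                    "p_raw": c.p_raw,
                    "p_bonferroni": c.p_adjusted,
                }
                for c in self.pairwise
            ]
        )


def size_anova(
    sizes: Sequence[float], groups: Sequence, pairwise: str = "pooled"
) -> SizeAnovaResult:
    """One-way ANOVA of centroid size with Bonferroni pairwise t-tests.

    ``pairwise="pooled"`` (default) uses the pooled residual variance
    from the full model with df = n−g for every pair;
    ``pairwise="per-pair"`` uses each pair's own pooled two-sample
    variance with df = nₐ+n_b−2.  Raw p-values are multiplied by the
    number of pairs and capped at 1.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(groups, dtype=object).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("sizes and groups length mismatch")
    classes: list = []
    for v in y:
        if v not in classes:
            classes.append(v)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    subs = {c: x[y == c] for c in classes}
    small = [c for c, s in subs.items() if len(s) < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")

    n, g = len(x), len(classes)
    grand = x.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in subs.values())
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in subs.values())
    df_b, df_w = g - 1, n - g
    ms_b = ss_between / df_b
    if ss_within == 0.0:
        f_stat, p = float("inf"), 0.0
        msw = 0.0
    else:
        msw = ss_within / df_w
        f_stat = ms_b / msw
        p = float(scipy.stats.f.sf(f_stat, df_b, df_w))

    n_pairs = g * (g - 1) // 2
    comps = []
    for a, b in itertools.combinations(classes, 2):
        sa, sb = subs[a], subs[b]
        if pairwise == "pooled":
            se2 = msw * (1.0 / len(sa) + 1.0 / len(sb))
            df = df_w
        elif pairwise == "per-pair":
            va, vb = sa.var(ddof=1), sb.var(ddof=1)
            df = len(sa) + len(sb) - 2
            sp2 = ((len(sa) - 1) * va + (len(sb) - 1) * vb) / df
            se2 = sp2 * (1.0 / len(sa) + 1.0 / len(sb))
        else:
            raise ValueError("pairwise must be 'pooled' or 'per-pair'")
        diff = sa.mean() - sb.mean()
        if se2 == 0.0:
            t = float("inf") if diff else 0.0
            p_raw = 0.0 if diff else 1.0
        else:
            t = diff / np.sqrt(se2)
            p_raw = float(2.0 * scipy.stats.t.sf(abs(t), df))
        comps.append(
            PairwiseComparison(a, b, float(t), float(df), p_raw, min(1.0, p_raw * n_pairs))
        )

    return SizeAnovaResult(
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={c: float(subs[c].mean()) for c in classes},
        pairwise=comps,
    )


@dataclass
class AllometryResult:
    r_squared: float
    p: float
    n_permutations: int
    seed: int
    observed_null_exceedances: int
    use_log: bool = True


def allometry_test(
    gpa: GPAResult,
    n_permutations: int = 1000,
    seed: int = 0,
    use_log: bool = True,
) -> AllometryResult:
    """Permutation test of the shape-on-size regression.

    Flattens the aligned shapes to an n × 2k response matrix, regresses
    on log CS (or raw CS with ``use_log=False``) by least squares, and
    reports R² = SS_fit / SS_total with sums of squares accumulated over
    all coordinate columns (Procrustes sums of squares).  The null is
    built by shuffling the size predictor across specimens;
    p = (#{R²_perm ≥ R²_obs} + 1) / (n_permutations + 1).
    """
    if gpa.n < 3:
        raise ValueError("allometry test needs at least 3 specimens")
    cs = np.asarray(gpa.centroid_sizes, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    x = np.log(cs) if use_log else cs.copy()
    if np.ptp(x) == 0.0:
        raise ValueError("centroid size is constant; allometric R² is undefined")

    yc = gpa.flat()
    yc = yc - yc.mean(axis=0)
    ss_total = float((yc**2).sum())
    if ss_total == 0.0:
        raise ValueError("shape data has zero variance")

    def r2(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        sxx = float(xc @ xc)
        return float((yc.T @ xc) @ (yc.T @ xc)) / (sxx * ss_total)

    xc = x - x.mean()
    sxx = float(xc @ xc)
    sxy = yc.T @ xc
    r2_obs = float(sxy @ sxy) / (sxx * ss_total)

    rng = np.random.default_rng(seed)
    # all permutations share Sxx; vectorize as one matrix product
    perms = np.empty((len(x), n_permutations))
    for p_i in range(n_permutations):
        perms[:, p_i] = rng.permutation(xc)
    proj = yc.T @ (perms - perms.mean(axis=0))  # (2k, P)
    r2_perm = (proj**2).sum(axis=0) / (sxx * ss_total)

    exceed = int((r2_perm >= r2_obs).sum())
    p = (exceed + 1) / (n_permutations + 1)
    return AllometryResult(
        r_squared=r2_obs,
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        observed_null_exceedances=exceed,
        use_log=use_log,
    )
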