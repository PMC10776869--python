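"""Optional rendering of discriminant ordinations (requires matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .discriminant import HullSet, convex_hulls

__all__ = ["plot_ld_scatter"]


def plot_ld_scatter(
    scores: np.ndarray,
    groups: Sequence,
    explained: Sequence[float] | None = None,
    hulls: bool = True,
    ax=None,
    path=None,
):
    """Scatter LD1 vs LD2 per group, with convex-hull envelopes.

    Returns the matplotlib Axes; when ``path`` is given the figure is
    also saved (format from the extension, e.g. ``.svg`` or ``.png``).
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pts = np.asarray(scores, dtype=float)[:, :2]
    y = np.asarray(groups, dtype=object).ravel()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    hull_set: HullSet | None = convex_hulls(pts, y) if hulls else None
    for g in dict.fromkeys(y):
        sub = pts[y == g]
        (line,) = ax.plot(sub[:, 0], sub[:, 1], "o", ms=4, alpha=0.8, label=str(g))
        if hull_set is not None and len(hull_set[g]) >= 3:
            closed = np.vstack([hull_set[g], hull_set[g][:1]])
            ax.fill(closed[:, 0], closed[:, 1], alpha=0.15, color=line.get_color())
            ax.plot(closed[:, 0], closed[:, 1], "-", lw=1, color=line.get_color())
    if explained is not None and len(explained) >= 2:
        ax.set_xlabel(f"LD1 ({explained[0] * 100:.0f}%)")
        ax.set_ylabel(f"LD2 ({explained[1] * 100:.0f}%)")
    else:
        ax.set_xlabel("LD1")
        ax.set_ylabel("LD2")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
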