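"""Stability of selected feature subsets across leave-one-subject-out folds.

For each fold the features are ranked by ascending p-value; the stability of a
subset size k is the fraction of the k top-ranked features common to *all*
folds. The curve of this fraction over k (often plotted against k/N) separates
feature families that select reproducible sets from those whose top ranks
churn with the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StabilityCurve",
    "default_k_grid",
    "top_k",
    "stability_fraction",
    "stability_curve",
    "stable_topk_links",
]


def default_k_grid(n_total: int) -> list[int]:
    """Powers of 2 from 2 to 2^14 plus the highlighted size 30, capped at N."""
    grid = sorted({2 ** e for e in range(1, 15)} | {30})
    return [k for k in grid if k <= n_total]


def top_k(p: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest p-values, in ascending-p order.

    Ties are broken by ascending feature index (stable sort), so the selection
    is deterministic.
    """
    p = np.asarray(p)
    if not 1 <= k <= len(p):
        raise ValueError(f"k must lie in 1..{len(p)}")
    order = np.argsort(p, kind="stable")
    return order[:k]


def stability_fraction(per_fold_topk: list[np.ndarray], k: int) -> float:
    """|intersection of the fold sets| / k."""
    if not per_fold_topk:
        raise ValueError("need at least one fold")
    sets = []
    for s in per_fold_topk:
        s = np.asarray(s)
        if len(s) != k:
            raise ValueError("every fold set must have size k")
        sets.append(set(s.tolist()))
    common = set.intersection(*sets)
    return len(common) / k


@dataclass
class StabilityCurve:
    """Fraction of common top-k features across folds, over a grid of k."""

    feature_type: str
    k_values: np.ndarray
    fraction_common: np.ndarray
    n_folds: int
    n_total: int

    @property
    def k_fraction(self) -> np.ndarray:
        """Normalized subset size k / N (the x-axis used for plotting)."""
        return self.k_values / self.n_total

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(100.0 * self.k_fraction, self.fraction_common, marker="o", **kwargs)
        ax.set_xlabel("% of total number of features (k/N)")
        ax.set_ylabel("fraction of features common to all folds")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"Feature-selection stability ({self.feature_type})")
        return ax


def stability_curve(
    per_fold_pvalues: list[np.ndarray],
    k_grid: list[int] | None = None,
    feature_type: str = "",
) -> StabilityCurve:
    """Overlap fraction over a grid of subset sizes.

    All folds must rank the same feature set; at k = N the fraction is exactly
    1 (every fold selects everything).
    """
    if not per_fold_pvalues:
        raise ValueError("need at least one fold")
    n_total = len(per_fold_pvalues[0])
    for p in per_fold_pvalues:
        if len(p) != n_total:
            raise ValueError("folds ranked different feature sets")
    if k_grid is None:
        k_grid = default_k_grid(n_total)
    k_values = np.asarray(sorted(set(int(k) for k in k_grid)))
    if np.any(k_values < 1) or np.any(k_values > n_total):
        raise ValueError("k values must lie in 1..N")
    fracs = np.empty(len(k_values))
    per_fold_order = [np.argsort(p, kind="stable") for p in per_fold_pvalues]
    for idx, k in enumerate(k_values):
        sets = [set(order[:k].tolist()) for order in per_fold_order]
        fracs[idx] = len(set.intersection(*sets)) / k
    return StabilityCurve(
        feature_type=feature_type,
        k_values=k_values,
        fraction_common=fracs,
        n_folds=len(per_fold_pvalues),
        n_total=n_total,
    )


def stable_topk_links(
    per_fold_topk: list[np.ndarray], descriptors: list | None = None
) -> tuple[np.ndarray, list]:
    """Intersection of fixed-size top-k sets across folds, with descriptors.

    Returns (sorted feature indices, matching descriptors) — e.g. the stable
    links common to every fold's 30 top-ranked link weights.
    """
    if not per_fold_topk:
        raise ValueError("need at least one fold")
    k = len(per_fold_topk[0])
    for s in per_fold_topk:
        if len(s) != k:
            raise ValueError("fixed k required across folds")
    common = set.intersection(*(set(np.asarray(s).tolist()) for s in per_fold_topk))
    idx = np.asarray(sorted(common), dtype=int)
    desc = [descriptors[i] for i in idx] if descriptors is not None else []
    return idx, desc
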