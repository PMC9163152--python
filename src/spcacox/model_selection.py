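"""Selection of the component count and the sparsity penalty.

Two criteria drive the sparse-PCA stage:

* the number of components k is the smallest count whose cumulative
  explained-variance fraction reaches a threshold (default 90%), evaluated
  on the unpenalized (dense) fit;
* the penalty lambda is the smallest grid value at which the fitted
  component supports are pairwise disjoint — each variable contributes to
  at most one component — with every component retaining at least one
  variable (an all-zero component means the penalty is too strong).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sparse_pca import SparsePCA


class DisjointSupportError(ValueError):
    """No grid value produced pairwise-disjoint, nonempty supports."""


def default_lambda_grid(num: int = 30, low: float = 1e-3, high: float = 10.0) -> np.ndarray:
    """Logarithmic grid spanning four decades on the per-subject objective scale."""
    return np.geomspace(low, high, num)


def validate_lambda_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(g) <= 0):
        raise ValueError("lambda grid must be strictly increasing")
    if g[0] < 0:
        raise ValueError("lambda grid values must be nonnegative")
    return g


def select_n_components(fractions, threshold: float = 0.90) -> int:
    """Smallest k whose cumulative explained-variance fraction reaches
    ``threshold``; all components (with a warning) if never reached."""
    f = np.asarray(fractions, dtype=float)
    if f.size == 0:
        raise ValueError("no explained-variance fractions supplied")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(f)
    hit = np.flatnonzero(cum >= threshold - 1e-12)
    if hit.size == 0:
        warnings.warn(
            f"cumulative explained variance ({cum[-1]:.3f}) never reaches "
            f"{threshold}; using all {f.size} components",
            stacklevel=2,
        )
        return int(f.size)
    return int(hit[0]) + 1


def _overlap_count(supports: list[np.ndarray]) -> int:
    """Number of variables appearing in more than one component support."""
    counts: dict[int, int] = {}
    for s in supports:
        for i in s:
            counts[int(i)] = counts.get(int(i), 0) + 1
    return sum(1 for c in counts.values() if c > 1)


@dataclass
class LambdaSelection:
    lambda_star: float
    fit: SparsePCA
    report: pd.DataFrame  # per-lambda: support sizes, overlapping variables, empty components


def select_lambda_disjoint(
    X,
    k: int,
    grid=None,
    penalty: str = "l1",
    l1_ratio: float = 0.95,
    support_tol: float = 1e-8,
    screen_max_iter: int = 300,
    **spca_kw,
) -> LambdaSelection:
    """Sweep the grid in increasing order; return the smallest lambda whose
    fit has pairwise-disjoint, all-nonempty component supports.

    Grid values are screened with a reduced iteration budget (supports
    settle long before the dense components stop rotating); a qualifying
    lambda is then refit at full precision and kept only if the converged
    supports still qualify, otherwise the sweep continues.
    """
    grid = validate_lambda_grid(default_lambda_grid() if grid is None else grid)
    rows = []
    chosen: tuple[float, SparsePCA] | None = None
    init = None  # warm start each grid fit from the previous lambda's solution

    def _inspect(fit: SparsePCA):
        supports = fit.support()
        n_empty = sum(1 for s in supports if s.size == 0)
        return supports, n_empty, _overlap_count(supports)

    for lam in grid:
        fit = SparsePCA(
            n_components=k, alpha=float(lam), penalty=penalty, l1_ratio=l1_ratio,
            support_tol=support_tol, init=init, max_iter=screen_max_iter, **spca_kw,
        ).fit(X)
        init = (fit.weights_, fit.ortho_)
        _, n_empty, overlap = _inspect(fit)
        if overlap == 0 and n_empty == 0:
            full = SparsePCA(
                n_components=k, alpha=float(lam), penalty=penalty, l1_ratio=l1_ratio,
                support_tol=support_tol, init=(fit.weights_, fit.ortho_), **spca_kw,
            ).fit(X)
            _, n_empty, overlap = _inspect(full)
            if overlap == 0 and n_empty == 0:
                fit = full
        supports = fit.support()
        rows.append({
            "lambda": float(lam),
            "support_sizes": "|".join(str(s.size) for s in supports),
            "total_support": int(sum(s.size for s in supports)),
            "overlapping_variables": overlap,
            "empty_components": n_empty,
        })
        if chosen is None and overlap == 0 and n_empty == 0:
            chosen = (float(lam), fit)
            break
    report = pd.DataFrame(rows)
    if chosen is None:
        detail = "; ".join(
            f"lambda={r['lambda']:.4g}: {r['overlapping_variables']} overlapping, "
            f"{r['empty_components']} empty" for r in rows
        )
        raise DisjointSupportError(
            f"no lambda in the grid yields disjoint nonempty supports ({detail})"
        )
    return LambdaSelection(lambda_star=chosen[0], fit=chosen[1], report=report)
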