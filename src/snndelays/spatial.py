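"""Moran's I spatial autocorrelation on receptive-field grids.

The global Moran's I of values ``x`` on ``N`` grid cells with spatial
weights ``w_ij`` (zero diagonal, total weight ``W``) is

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

Under no spatial autocorrelation its expectation is ``-1/(N-1)``.  Weights
here are the Queen's case: two cells are neighbours iff their Chebyshev
distance on the grid is 1 (all 8 surrounding cells).

Because the ordering of neurons along the spatial axis of a receptive
field is arbitrary, the autocorrelation of a pattern is assessed as the
*maximum* Moran's I over random row permutations of the matrix (the
identity permutation always included).  Distributions of these maxima
(e.g. trained vs. untrained networks) are compared with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "SpatialWeightMatrix",
    "MoranResult",
    "queen_weights",
    "morans_i",
    "max_permuted_morans",
    "compare_morans_distributions",
]


@dataclass
class SpatialWeightMatrix:
    """Binary adjacency over the cells of an ``n_rows x n_cols`` grid.

    Cells are indexed row-major; the adjacency is symmetric with a zero
    diagonal.  ``W`` is the sum of all entries.
    """

    adjacency: sp.csr_matrix
    n_rows: int
    n_cols: int

    @property
    def W(self) -> float:
        return float(self.adjacency.sum())

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def queen_weights(n_rows: int, n_cols: int) -> SpatialWeightMatrix:
    """Queen's-case (8-neighbour) adjacency for a grid.

    Built from the identity that Queen adjacency factorises over axes:
    cells are neighbours iff both row and column offsets are in
    ``{-1, 0, 1}``, excluding the cell itself.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")

    def band(n: int) -> sp.csr_matrix:
        # tridiagonal-with-diagonal: |offset| <= 1
        return sp.diags(
            [np.ones(n - 1), np.ones(n), np.ones(n - 1)], [-1, 0, 1], format="csr"
        ) if n > 1 else sp.csr_matrix(np.ones((1, 1)))

    adj = sp.kron(band(n_rows), band(n_cols), format="csr")
    adj = adj - sp.eye(n_rows * n_cols, format="csr")
    adj.eliminate_zeros()
    return SpatialWeightMatrix(adjacency=adj.tocsr(), n_rows=n_rows, n_cols=n_cols)


def morans_i(x: np.ndarray, w: SpatialWeightMatrix) -> float:
    """Global Moran's I of a grid of values.

    Raises on a constant grid (the variance denominator vanishes).
    """
    x = np.asarray(x, dtype=float)
    if x.size != w.n_cells:
        raise ValueError(f"grid has {x.size} cells, weights expect {w.n_cells}")
    if x.size < 2:
        raise ValueError("need at least 2 cells")
    xc = x.ravel() - x.mean()
    den = float(xc @ xc)
    if den == 0.0:
        raise ValueError("Moran's I undefined for a constant grid (zero variance)")
    num = float(xc @ (w.adjacency @ xc))
    return (x.size / w.W) * num / den


@dataclass
class MoranResult:
    """Moran's I of a pattern and its maximum over row permutations."""

    i_value: float
    i_max_permuted: float
    n_permutations: int
    null_baseline: float
    seed: int | None = None


def max_permuted_morans(
    x: np.ndarray,
    w: SpatialWeightMatrix,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Maximum Moran's I over random row permutations of a matrix.

    The rows (the neuron axis, whose ordering is arbitrary) are permuted;
    the identity ordering is always included, so the reported maximum is
    at least the unpermuted value.  Deterministic given the seed.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {x.shape}")
    R, C = x.shape
    if (R, C) != (w.n_rows, w.n_cols):
        raise ValueError(f"matrix shape {x.shape} != weight grid ({w.n_rows}, {w.n_cols})")

    i0 = morans_i(x, w)
    if n_perm == 0:
        return MoranResult(i0, i0, 0, -1.0 / (x.size - 1), seed)

    perms = np.empty((n_perm, R), dtype=int)
    for p in range(n_perm):
        perms[p] = rng.permutation(R)
    Xp = x[perms].reshape(n_perm, R * C)
    xc = Xp - Xp.mean(axis=1, keepdims=True)
    den = np.einsum("pn,pn->p", xc, xc)  # identical across permutations
    num = np.einsum("pn,pn->p", xc, (w.adjacency @ xc.T).T)
    i_perm = (x.size / w.W) * num / den
    i_max = float(max(i0, i_perm.max()))
    return MoranResult(
        i_value=i0,
        i_max_permuted=i_max,
        n_permutations=n_perm,
        null_baseline=-1.0 / (x.size - 1),
        seed=seed,
    )


def compare_morans_distributions(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples of Moran's I values.

    Returns ``(U, p)`` with U reported for sample ``a``.  Uses exact
    enumeration for small tie-free samples and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
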