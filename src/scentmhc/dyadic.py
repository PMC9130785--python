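"""Permutation tests on dyadic distance matrices.

Within-sex (square) matrices are compared with a partial Mantel test:
the statistic is the partial Pearson correlation of the unfolded strict
lower triangles of the chemical matrix A and the genetic matrix B,
controlling for one or more covariate matrices C (here the other
chemical component and the breeding-status difference matrix). The null
distribution permutes individuals — a simultaneous random row-and-column
permutation of A, recomputing the partial statistic each draw, with B
and C held fixed.

Mixed-sex (rectangular, males x females) matrices cannot enter a Mantel
test, so a Spearman partial correlation permutation test is used: the
statistic is the partial Pearson correlation of the average-ranked
unfolded vectors, and the default null permutes the dyad entries of A's
unfolded vector (the convention of rank-based partial-correlation
permutation tests). A restricted null that permutes A's row labels is
available because dyad-entry permutation ignores the non-independence
of dyads sharing an individual.

All p-values use the add-one estimator p = (#{as extreme} + 1)/(B + 1),
so the smallest attainable p is 1/(B + 1) and p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .dyads import RECT, SQUARE, DyadMatrix

_EPS = 1e-12


@dataclass
class TestResult:
    """Outcome of one dyadic permutation test."""

    __test__ = False  # not a pytest collection target

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    tail: str
    seed: int
    n_dyads: int
    adjusted_alpha: float | None = None

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - _EPS
        assert abs(self.statistic) <= 1 + 1e-9

    @property
    def significant(self) -> bool | None:
        if self.adjusted_alpha is None:
            return None
        return self.p_value < self.adjusted_alpha


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------
# partial correlation


def _as_cov_list(c) -> list[np.ndarray]:
    """One covariate vector, or a sequence of them, to a list of arrays."""
    if c is None:
        return []
    arr = np.asarray(c, dtype=float)
    if arr.ndim == 1:
        return [arr]
    if arr.ndim == 2:
        return [row for row in arr]
    raise ValueError("covariates must be a vector or a sequence of vectors")


def _residual_basis(covs: list[np.ndarray], n: int) -> np.ndarray:
    """Orthonormal basis of span{1, covariates} for residualization."""
    z = np.column_stack([np.ones(n)] + covs)
    q, r = np.linalg.qr(z)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx <= _EPS or ny <= _EPS:
        raise ValueError("partial correlation undefined: a vector is constant "
                         "after removing the covariates")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def partial_pearson(x: Sequence[float], y: Sequence[float], z=None) -> float:
    """Partial Pearson correlation of x and y given covariate(s) z.

    Computed by residualizing x and y on [1, z] and correlating the
    residuals; for a single covariate this equals the textbook formula
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)). With no
    covariate it reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covs = _as_cov_list(z)
    n = x.size
    if y.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must share one length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()
            and all(np.isfinite(c).all() for c in covs)):
        raise ValueError("inputs must be finite")
    q = _residual_basis(covs, n)
    xr = x - q @ (q.T @ x)
    yr = y - q @ (q.T @ y)
    return _corr(xr, yr)


# ---------------------------------------------------------------------
# permutation machinery


def _aligned_unfolds(a: DyadMatrix, b: DyadMatrix, c) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    covs = [c] if isinstance(c, DyadMatrix) else list(c or [])
    bu = b.align_to(a).unfold()
    cu = [m.align_to(a).unfold() for m in covs]
    return a.unfold(), bu, cu


def _perm_pvalue(obs: float, perm: np.ndarray, tail: str) -> float:
    if tail == "two-sided":
        extreme = np.sum(np.abs(perm) >= abs(obs) - _EPS)
    elif tail == "greater":
        extreme = np.sum(perm >= obs - _EPS)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((extreme + 1) / (perm.size + 1))


def _batched_partial_corr(a_perm: np.ndarray, y_res: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Partial corr of each row of a_perm with y given basis q."""
    a_res = a_perm - (a_perm @ q) @ q.T
    num = a_res @ y_res
    den = np.linalg.norm(a_res, axis=1) * np.linalg.norm(y_res)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~np.isfinite(out)] = 0.0
    return np.clip(out, -1.0, 1.0)


def partial_mantel(
    a: DyadMatrix,
    b: DyadMatrix,
    c: DyadMatrix | Sequence[DyadMatrix] | None = None,
    n_perm: int = 10_000,
    tail: str = "two-sided",
    seed: int = 0,
    _chunk: int = 2_000,
) -> TestResult:
    """(Partial) Mantel test between square distance matrices.

    ``a`` is the matrix whose rows and columns are permuted (the
    chemical distances); ``b`` the genetic distances; ``c`` zero or
    more covariate matrices. With ``c=None`` this is the simple Mantel
    test. Two-sided by default; ``tail='greater'`` tests positive
    covariance only.
    """
    if a.kind != SQUARE or b.kind != SQUARE:
        raise ValueError("partial_mantel needs square DyadMatrix inputs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    au, bu, cu = _aligned_unfolds(a, b, c)
    n = len(a.row_ids)
    q = _residual_basis(cu, au.size)
    y_res = bu - q @ (q.T @ bu)
    x_res = au - q @ (q.T @ au)
    obs = _corr(x_res, y_res)
    if np.linalg.norm(y_res) <= _EPS:
        raise ValueError("genetic matrix constant after covariate removal")

    rng = np.random.default_rng(seed)
    iu, ju = np.tril_indices(n, k=-1)
    perm_stats = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(k)])
        a_perm = a.values[perms[:, iu], perms[:, ju]]
        perm_stats[done:done + k] = _batched_partial_corr(a_perm, y_res, q)
        done += k
    name = "partial Mantel r" if cu else "Mantel r"
    return TestResult(name, obs, _perm_pvalue(obs, perm_stats, tail),
                      n_perm, tail, seed, au.size)


def mantel(a: DyadMatrix, b: DyadMatrix, n_perm: int = 10_000,
           tail: str = "two-sided", seed: int = 0) -> TestResult:
    """Simple Mantel test (no covariates)."""
    return partial_mantel(a, b, None, n_perm=n_perm, tail=tail, seed=seed)


def partial_spearman_rect(
    a: DyadMatrix,
    b: DyadMatrix,
    c: DyadMatrix | Sequence[DyadMatrix] | None = None,
    n_perm: int = 10_000,
    tail: str = "two-sided",
    seed: int = 0,
    restricted: bool = False,
    _chunk: int = 2_000,
) -> TestResult:
    """Spearman partial correlation permutation test on rectangular dyads.

    The statistic is the partial Pearson correlation of the
    average-ranked unfolded vectors (partial Spearman rho). The default
    null permutes A's dyad entries; ``restricted=True`` permutes A's
    row labels instead, preserving the row-block structure.
    """
    if a.kind != RECT or b.kind != RECT:
        raise ValueError("partial_spearman_rect needs rectangular DyadMatrix inputs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    au, bu, cu = _aligned_unfolds(a, b, c)
    if np.ptp(au) <= _EPS:
        raise ValueError("chemical matrix is constant: ranks undefined")
    ra = rankdata(au)
    rb = rankdata(bu)
    rc = [rankdata(v) for v in cu]
    q = _residual_basis(rc, ra.size)
    y_res = rb - q @ (q.T @ rb)
    x_res = ra - q @ (q.T @ ra)
    obs = _corr(x_res, y_res)

    rng = np.random.default_rng(seed)
    nrow, ncol = len(a.row_ids), len(a.col_ids)
    perm_stats = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_chunk, n_perm - done)
        if restricted:
            # permuting row labels permutes rank-vector entries blockwise
            perms = np.array([rng.permutation(nrow) for _ in range(k)])
            idx = (perms[:, :, None] * ncol + np.arange(ncol)[None, None, :]).reshape(k, -1)
        else:
            idx = np.array([rng.permutation(ra.size) for _ in range(k)])
        perm_stats[done:done + k] = _batched_partial_corr(ra[idx], y_res, q)
        done += k
    name = "partial Spearman rho" if cu else "Spearman rho"
    return TestResult(name, obs, _perm_pvalue(obs, perm_stats, tail),
                      n_perm, tail, seed, au.size)
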