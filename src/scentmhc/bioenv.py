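"""BIO-ENV: exhaustive compound-subset selection against a genetic target.

For every subset of at most ``k_max`` compounds, compute the Euclidean
distance between individuals on the subset's (log-profile) columns,
unfold it onto the dyad ordering of the target genetic distance matrix,
and correlate the two dyad vectors. The best subset per size and the
overall best are reported. Enumeration is exhaustive with a
deterministic tie-break (lexicographically smallest compound subset by
label), so results are invariant to column order.

The search correlation defaults to plain Pearson Mantel r; a Spearman
variant and a partial variant controlling a covariate matrix (e.g.
breeding-status distance) are available and flagged in the result.

Selection bias caveat: the maximized correlation is an optimistic
estimate and must not be read as a tested hypothesis; no significance
test of the selected subset is provided by design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dyadic import _residual_basis
from .dyads import SQUARE, DyadMatrix

_EPS = 1e-12


@dataclass
class BioEnvResult:
    """Best compound subsets per size and overall."""

    per_size: dict[int, tuple[tuple[str, ...], float]]
    best_subset: tuple[str, ...]
    best_correlation: float
    correlation: str
    n_subsets_evaluated: int
    partial: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "correlation": r, "compounds": ", ".join(sub)}
            for k, (sub, r) in sorted(self.per_size.items())
        ]
        return pd.DataFrame(rows)


def _pairwise_sq_diffs(x: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """Per-column squared dyad differences, shape (p, n_dyads)."""
    return (x[iu, :] - x[ju, :]).T ** 2


def bioenv(
    profiles: pd.DataFrame,
    target: DyadMatrix,
    k_max: int = 6,
    correlation: str = "mantel_pearson",
    scale: bool = False,
    covariate: DyadMatrix | None = None,
    _chunk: int = 20_000,
) -> BioEnvResult:
    """Exhaustive BIO-ENV search.

    ``profiles``: per-individual chemical profile (rows must cover the
    target's labels). ``scale`` z-scores the compound columns before
    computing subset distances (the classic procedure's normalization,
    off by default: log profiles are already on comparable scales).
    """
    if target.kind != SQUARE:
        raise ValueError("bioenv target must be a square DyadMatrix")
    labels = list(target.row_ids)
    missing = [l for l in labels if l not in set(profiles.index.astype(str))]
    if missing:
        raise ValueError(f"profiles missing individuals: {missing}")
    prof = profiles.copy()
    prof.index = prof.index.astype(str)
    prof = prof.loc[labels]
    # canonical column order: sorted labels -> order-invariant tie-break
    cols = sorted(prof.columns.astype(str))
    p = len(cols)
    if not 1 <= k_max <= p:
        raise ValueError(f"k_max must lie in [1, {p}]")
    x = prof[cols].to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    n = len(labels)
    iu, ju = np.tril_indices(n, k=-1)
    d2 = _pairwise_sq_diffs(x, iu, ju)  # (p, n_dyads)
    t = target.unfold()
    if np.ptp(t) <= _EPS:
        raise ValueError("constant target matrix: correlations undefined")

    use_rank = correlation == "mantel_spearman"
    if correlation not in ("mantel_pearson", "mantel_spearman"):
        raise ValueError(f"unknown correlation {correlation!r}")
    cov_u = None
    if covariate is not None:
        cov_u = covariate.align_to(target).unfold()
        if use_rank:
            cov_u = rankdata(cov_u)
    tv = rankdata(t) if use_rank else t
    q = _residual_basis([cov_u] if cov_u is not None else [], tv.size)
    y_res = tv - q @ (q.T @ tv)
    y_norm = np.linalg.norm(y_res)
    if y_norm <= _EPS:
        raise ValueError("target constant after covariate removal")

    per_size: dict[int, tuple[tuple[str, ...], float]] = {}
    n_eval = 0
    for k in range(1, k_max + 1):
        best_r, best_sub = -np.inf, None
        combos = itertools.combinations(range(p), k)
        while True:
            batch = list(itertools.islice(combos, _chunk))
            if not batch:
                break
            idx = np.asarray(batch)  # (m, k)
            dist = np.sqrt(d2[idx].sum(axis=1))  # (m, n_dyads)
            if use_rank:
                dist = rankdata(dist, axis=1)
            x_res = dist - (dist @ q) @ q.T
            num = x_res @ y_res
            den = np.linalg.norm(x_res, axis=1) * y_norm
            with np.errstate(invalid="ignore", divide="ignore"):
                r = num / den
            r[~np.isfinite(r)] = -np.inf
            j = int(np.argmax(r))
            # combinations arrive lexicographically: first max wins ties
            if r[j] > best_r + _EPS:
                best_r, best_sub = float(r[j]), tuple(cols[i] for i in batch[j])
            n_eval += len(batch)
        per_size[k] = (best_sub, best_r)

    best_k = max(per_size, key=lambda k: (per_size[k][1], -k))
    # overall tie-break: highest r; at equal r, the smaller subset
    best_sub, best_r = per_size[best_k]
    for k in sorted(per_size):
        sub, r = per_size[k]
        if r > best_r + _EPS:
            best_sub, best_r = sub, r
    assert n_eval == sum(comb(p, k) for k in range(1, k_max + 1))
    return BioEnvResult(per_size, best_sub, best_r, correlation, n_eval,
                        partial=covariate is not None)


def prefilter_compounds(
    profiles: pd.DataFrame, target: DyadMatrix, n_keep: int
) -> list[str]:
    """Rank compounds by |single-compound dyadic correlation| with the target.

    A cheap screen for very wide profiles before the exhaustive search:
    keeps the ``n_keep`` compounds whose own |difference| dyad vector
    correlates most strongly (in absolute value) with the target. The
    screen is marginal — compounds useful only in combination can be
    lost — so results after pre-filtering are labelled as such.
    """
    labels = list(target.row_ids)
    prof = profiles.copy()
    prof.index = prof.index.astype(str)
    x = prof.loc[labels].to_numpy(dtype=float)
    n = len(labels)
    iu, ju = np.tril_indices(n, k=-1)
    d = np.abs(x[iu, :] - x[ju, :]).T  # (p, n_dyads)
    t = target.unfold()
    t = t - t.mean()
    dc = d - d.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc @ t) / (np.linalg.norm(dc, axis=1) * np.linalg.norm(t))
    r[~np.isfinite(r)] = 0.0
    order = np.argsort(-np.abs(r), kind="stable")[:n_keep]
    cols = list(prof.columns.astype(str))
    return sorted(cols[k] for k in order)


def bioenv_greedy(
    profiles: pd.DataFrame,
    target: DyadMatrix,
    k_max: int = 6,
    correlation: str = "mantel_pearson",
    scale: bool = False,
    covariate: DyadMatrix | None = None,
) -> BioEnvResult:
    """Greedy forward-selection variant — NOT exhaustive.

    Adds at each step the compound that most improves the correlation;
    returns the best prefix subset. Use when the exhaustive search is
    out of reach; the result is a heuristic with no optimality
    guarantee and is flagged by ``correlation`` suffix ``+greedy``.
    """
    cols = sorted(profiles.columns.astype(str))
    chosen: list[str] = []
    per_size: dict[int, tuple[tuple[str, ...], float]] = {}
    n_eval = 0
    for k in range(1, min(k_max, len(cols)) + 1):
        best_col, best_r = None, -np.inf
        for c in cols:
            if c in chosen:
                continue
            sub = sorted(chosen + [c])
            res = bioenv(profiles[sub], target, k_max=len(sub),
                         correlation=correlation, scale=scale,
                         covariate=covariate)
            r = res.per_size[len(sub)][1]
            n_eval += 1
            if r > best_r + _EPS or (r > best_r - _EPS and
                                     (best_col is None or c < best_col)):
                best_col, best_r = c, r
        chosen.append(best_col)
        per_size[k] = (tuple(sorted(chosen)), best_r)
    best_k = max(per_size, key=lambda k: (per_size[k][1], -k))
    best_sub, best_r = per_size[best_k]
    return BioEnvResult(per_size, best_sub, best_r, correlation + "+greedy",
                        n_eval, partial=covariate is not None)
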