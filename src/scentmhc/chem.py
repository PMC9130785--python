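"""Chemical peak-table processing, PCA and chemical distance matrices.

The pipeline starts from a replicate-level GC–MS peak table (one row per
bird x replicate, one column per compound peak area, plus the sample
mass and the internal-standard peak area that normalize instrument
drift) and produces per-bird profiles and principal-component scores:

1. standardize each replicate: area / (internal-standard area x mass);
2. average replicates to one vector per bird;
3. log(X + 1)-transform (tames the few highly abundant compounds);
4. PCA on the bird x compound profile matrix;
5. dyadic |score difference| matrices per retained component.

The order standardize -> average -> log is fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dyads import DyadMatrix, split_by_sex

logger = logging.getLogger(__name__)

#: Non-compound columns of a peak table.
META_COLUMNS = ("individual", "replicate", "sample_mass", "internal_standard_area")


def compound_columns(peak_table: pd.DataFrame) -> list[str]:
    return [c for c in peak_table.columns if c not in META_COLUMNS]


def standardize_replicate(
    areas: np.ndarray, internal_standard_area: float, sample_mass: float,
    label: str = "replicate",
) -> np.ndarray:
    """area / (internal-standard area x sample mass); units g^-1."""
    if not internal_standard_area > 0:
        raise ValueError(f"{label}: internal-standard area must be > 0")
    if not sample_mass > 0:
        raise ValueError(f"{label}: sample mass must be > 0")
    return np.asarray(areas, dtype=float) / (internal_standard_area * sample_mass)


def aggregate_individuals(peak_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level peak table -> per-bird log profile (ChemProfile).

    Standardizes every replicate, averages within bird, then applies
    log(X + 1) entrywise. Returns a DataFrame indexed by individual id
    (input order of first appearance), one column per compound.
    """
    comps = compound_columns(peak_table)
    if not comps:
        raise ValueError("peak table has no compound columns")
    std_rows = []
    for _, row in peak_table.iterrows():
        label = f"individual {row['individual']} replicate {row['replicate']}"
        std_rows.append(
            standardize_replicate(
                row[comps].to_numpy(dtype=float),
                float(row["internal_standard_area"]),
                float(row["sample_mass"]),
                label=label,
            )
        )
    std = pd.DataFrame(std_rows, columns=comps)
    std["individual"] = peak_table["individual"].astype(str).to_numpy()
    order = std["individual"].drop_duplicates().tolist()
    means = std.groupby("individual", sort=False).mean().loc[order]
    return np.log1p(means)


@dataclass
class PCScores:
    """PCA result: per-bird scores, variance structure, loadings.

    ``scores`` is individuals x components (columns PC1, PC2, ...);
    ``loadings`` the unit-norm eigenvectors (compounds x components);
    ``correlations`` the compound-component correlations; eigenvalues
    use the n-1 denominator. Components are sign-fixed so that each
    component's largest-magnitude loading is positive.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    loadings: pd.DataFrame
    correlations: pd.DataFrame
    scaled: bool

    def strong_compounds(self, component: str, threshold: float = 0.7) -> list[str]:
        """Compounds with |compound-component correlation| >= threshold."""
        r = self.correlations[component]
        return list(r.index[np.abs(r.to_numpy()) >= threshold])


def run_pca(profiles: pd.DataFrame, scale: bool = True) -> PCScores:
    """PCA of a per-bird chemical profile matrix.

    ``scale=True`` (default) works on the correlation structure:
    columns are centered and divided by their sample s.d.; columns with
    zero variance are dropped with a warning. ``scale=False`` uses the
    covariance structure (centering only).
    """
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles contain missing values")
    n, p = profiles.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 individuals")
    if p < 2:
        raise ValueError("PCA needs at least 2 compounds")
    x = profiles.to_numpy(dtype=float)
    cols = list(profiles.columns)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"dropping zero-variance compounds before scaling: {dropped}")
            logger.warning("run_pca: dropped zero-variance compounds %s", dropped)
            x, cols, sd = x[:, keep], [c for c, k in zip(cols, keep) if k], sd[keep]
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ncomp = min(n - 1, len(cols))
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(ncomp), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = (u * s) * flip[None, :]
    eig = s**2 / (n - 1)
    names = [f"PC{k + 1}" for k in range(ncomp)]
    scores_df = pd.DataFrame(scores, index=profiles.index, columns=names)
    loadings = pd.DataFrame(vt.T, index=cols, columns=names)
    col_sd = x.std(axis=0, ddof=1)
    sc_sd = scores.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x.T @ scores) / (n - 1) / np.outer(col_sd, sc_sd)
    corr_df = pd.DataFrame(corr, index=cols, columns=names)
    # centering makes rank <= n-1, so the kept eigenvalues carry the trace
    return PCScores(
        scores=scores_df,
        eigenvalues=eig,
        variance_fraction=eig / eig.sum(),
        loadings=loadings,
        correlations=corr_df,
        scaled=scale,
    )


# ---------------------------------------------------------------------
# component retention


def kaiser_guttman(eigenvalues: np.ndarray) -> int:
    """Number of eigenvalues above the mean eigenvalue."""
    eig = np.asarray(eigenvalues, dtype=float)
    return int(np.sum(eig > eig.mean()))


def broken_stick_thresholds(p: int) -> np.ndarray:
    """Expected eigenvalue fractions b_k = (1/p) sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Components whose variance fraction beats the broken-stick model.

    Counts leading components only: stops at the first component below
    its threshold.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    frac = eig / eig.sum()
    thresh = broken_stick_thresholds(len(eig))
    k = 0
    for f, b in zip(frac, thresh):
        if f > b:
            k += 1
        else:
            break
    return k


def parallel_analysis(
    eigenvalues: np.ndarray, n_samples: int, n_variables: int | None = None,
    n_sim: int = 199, quantile: float = 0.95, seed: int = 0,
) -> int:
    """Horn's parallel analysis against correlation-matrix null spectra.

    Simulates ``n_sim`` standard-normal datasets of the same shape,
    takes the per-rank ``quantile`` of their correlation-PCA
    eigenvalues, and retains leading observed components exceeding it.
    Observed eigenvalues are rescaled to sum to the variable count so
    covariance-based spectra are compared on the null's scale.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    p = n_variables if n_variables is not None else len(eig)
    m = len(eig)
    eig = eig * (p / eig.sum())
    rng = np.random.default_rng(seed)
    null = np.empty((n_sim, m))
    for b in range(n_sim):
        x = rng.standard_normal((n_samples, p))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        s = np.linalg.svd(x, compute_uv=False)
        lam = s**2 / (n_samples - 1)
        null[b] = lam[:m]
    cut = np.quantile(null, quantile, axis=0)
    k = 0
    for lam, c in zip(eig, cut):
        if lam > c:
            k += 1
        else:
            break
    return k


def retain_components(
    eigenvalues: np.ndarray,
    n_samples: int | None = None,
    n_variables: int | None = None,
    override: int | None = None,
    n_sim: int = 199,
    seed: int = 0,
) -> int:
    """Recommend how many components to retain.

    Applies Kaiser–Guttman, broken-stick and (when ``n_samples`` is
    given) Horn's parallel analysis and returns the median
    recommendation; ``override`` short-circuits all criteria (the
    published storm-petrel analysis is reproduced with ``override=2``).
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue vector")
    if np.any(eig < 0) or np.any(np.diff(eig) > 1e-10):
        raise ValueError("eigenvalues must be nonnegative and non-increasing")
    if override is not None:
        if override < 1:
            raise ValueError("override must be >= 1")
        return int(override)
    recs = [kaiser_guttman(eig), broken_stick(eig)]
    if n_samples is not None:
        recs.append(parallel_analysis(eig, n_samples, n_variables, n_sim=n_sim, seed=seed))
    return int(np.median(recs))


# ---------------------------------------------------------------------
# dyadic chemical distances


def pc_distance_matrices(
    scores: PCScores | pd.DataFrame, sexes: Sequence[str], component: str | int
) -> dict[str, DyadMatrix]:
    """FF / MM / MF |score difference| matrices for one component.

    ``sexes`` aligns with the score rows; ``component`` is a column
    name ('PC1') or 0-based index.
    """
    frame = scores.scores if isinstance(scores, PCScores) else scores
    col = frame.columns[component] if isinstance(component, int) else component
    return split_by_sex(frame[col].to_numpy(), list(frame.index.astype(str)), sexes)


# ---------------------------------------------------------------------
# IO


def read_peak_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    tab["individual"] = tab["individual"].astype(str)
    return tab


def write_pca_report(pcs: PCScores, out_dir: str | Path, n_components: int | None = None) -> None:
    """Write scores / loadings / variance-fraction TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = n_components or pcs.scores.shape[1]
    cols = pcs.scores.columns[:k]
    pcs.scores[cols].to_csv(out / "pca_scores.tsv", sep="\t", index_label="individual",
                            float_format="%.10g")
    pcs.loadings[cols].to_csv(out / "pca_loadings.tsv", sep="\t", index_label="compound",
                              float_format="%.10g")
    pd.DataFrame(
        {"eigenvalue": pcs.eigenvalues[:k], "variance_fraction": pcs.variance_fraction[:k]},
        index=cols,
    ).to_csv(out / "pca_variance.tsv", sep="\t", index_label="component", float_format="%.10g")
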