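"""Seeded simulation studies: type-I error, power, subset recovery.

These functions run the full generator -> chemistry -> genetics ->
permutation-test chain over many independent cohorts and report
operating characteristics of the dyadic analysis:

* :func:`null_rejection_rate` — with ``effect_size=0`` the chemical and
  genetic matrices are independent, so the F–F partial Mantel test
  should reject at close to its nominal level;
* :func:`power_rate` — with a strong planted effect the same test on
  signal-compound distances should reject nearly always;
* :func:`bioenv_recovery_rate` — the BIO-ENV search should recover the
  planted signal compounds.

Per-cohort seeds are spawned from a single master seed via one RNG, so
every study is reproducible end to end and all seeds stay below 2^31.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .bioenv import bioenv
from .chem import aggregate_individuals, pc_distance_matrices, run_pca
from .dyadic import partial_mantel
from .dyads import DyadMatrix, split_by_sex
from .mhc import build_mhc_matrices
from .simulate import SimConfig, SimulatedStudy, generate_cohort

#: Strong-effect generator settings used by the power and recovery
#: studies (defaults chosen for test power, as the generator's own
#: calibration, not as an estimate of field effect sizes).
STRONG_EFFECT = dict(
    n_per_sex=20,
    n_compounds=20,
    n_signal_compounds=3,
    alleles_per_locus=5,
    seq_length=40,
    effect_size=3.0,
    diversity_effect=0.5,
    noise_sd=0.2,
    genotype_coherence=0.85,
)

#: Dyadic target of the strong-effect studies: the class IIB locus whose
#: F-F covariance the emulated design is most sensitive to.
STRONG_LOCUS = "DAB2"



def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n (cohort, test) seed pairs; data and permutation streams stay apart."""
    return np.random.default_rng(seed).integers(2**31, size=(n, 2))


def _status_ff(study: SimulatedStudy) -> DyadMatrix:
    gt = study.genotype_table
    status = (gt["sample_day"] - gt["hatch_day"]).to_numpy()
    return split_by_sex(status, gt["individual"], gt["sex"])["FF"]


def _signal_distance_ff(study: SimulatedStudy) -> DyadMatrix:
    """Euclidean F–F distance on the planted signal compounds' log profile."""
    prof = aggregate_individuals(study.peak_table)
    gt = study.genotype_table.set_index("individual")
    females = [i for i in prof.index if gt.loc[i, "sex"] == "F"]
    x = prof.loc[females, study.truth["signal_compounds"]].to_numpy()
    return DyadMatrix.square(squareform(pdist(x)), females)


def null_rejection_rate(
    n_cohorts: int = 500,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    n_per_sex: int = 20,
    n_compounds: int = 30,
) -> float:
    """Type-I error of the F–F partial Mantel test under the null.

    Each cohort is generated with ``effect_size=0`` (chemistry carries
    no MHC information); the test correlates F–F PC1 chemical distance
    with F–F both-loci MHC distance, controlling PC2 distance and the
    breeding-status difference matrix.
    """
    seeds = _spawn_seeds(seed, n_cohorts)
    hits = 0
    for s, s_test in seeds:
        cfg = SimConfig(n_per_sex=n_per_sex, n_compounds=n_compounds,
                        n_signal_compounds=1, effect_size=0.0,
                        alleles_per_locus=5, seq_length=40, seed=int(s))
        study = generate_cohort(cfg)
        prof = aggregate_individuals(study.peak_table)
        pcs = run_pca(prof, scale=True)
        gt = study.genotype_table
        sex = gt.set_index("individual").loc[prof.index, "sex"].tolist()
        pc1 = pc_distance_matrices(pcs, sex, "PC1")["FF"]
        pc2 = pc_distance_matrices(pcs, sex, "PC2")["FF"]
        mhc = build_mhc_matrices(study.genotypes, "both", "max")["FF"]
        res = partial_mantel(pc1, mhc, [pc2, _status_ff(study)],
                             n_perm=n_perm, seed=int(s_test))
        hits += res.p_value < alpha
    return hits / n_cohorts


def power_rate(
    n_cohorts: int = 100,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Rejection rate of the F–F partial Mantel under a strong effect.

    Chemical distance is the Euclidean distance on the planted signal
    compounds; genetic distance is both-loci max MHC distance; the
    breeding-status difference matrix is the covariate.
    """
    seeds = _spawn_seeds(seed, n_cohorts)
    hits = 0
    for s, s_test in seeds:
        cfg = SimConfig(seed=int(s), **STRONG_EFFECT)
        study = generate_cohort(cfg)
        chem_ff = _signal_distance_ff(study)
        mhc = build_mhc_matrices(study.genotypes, STRONG_LOCUS, "max")["FF"]
        res = partial_mantel(chem_ff, mhc, [_status_ff(study)],
                             n_perm=n_perm, seed=int(s_test))
        hits += res.p_value < alpha
    return hits / n_cohorts


def bioenv_recovery_rate(
    n_runs: int = 100,
    k_max: int = 6,
    min_recovered: int = 2,
    seed: int = 2,
) -> float:
    """Fraction of runs whose BIO-ENV best subset recovers the signal.

    Each run plants 3 signal compounds among 20, searches F–F profiles
    against both-loci MHC distance with subsets up to ``k_max``, and
    succeeds when at least ``min_recovered`` planted compounds appear
    in the best subset.
    """
    seeds = _spawn_seeds(seed, n_runs)
    hits = 0
    for s, _ in seeds:
        cfg = SimConfig(seed=int(s), **STRONG_EFFECT)
        study = generate_cohort(cfg)
        prof = aggregate_individuals(study.peak_table)
        gt = study.genotype_table.set_index("individual")
        females = [i for i in prof.index if gt.loc[i, "sex"] == "F"]
        mhc = build_mhc_matrices(study.genotypes, STRONG_LOCUS, "max")["FF"]
        res = bioenv(prof.loc[females], mhc, k_max=k_max)
        hit = len(set(res.best_subset) & set(study.truth["signal_compounds"]))
        hits += hit >= min_recovered
    return hits / n_runs
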