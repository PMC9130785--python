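"""Synthetic cohorts with the dyadic odour–gene covariance structure.

The generator emulates the study design the analysis assumes: a
sex-balanced cohort of incubating adults, diploid genotypes at two MHC
class IIB loci drawn from a finite allele pool, and a replicate-level
GC–MS peak table whose compound abundances can depend on the MHC.

Measurement model (log scale, per compound c, individual i, replicate r):

    log conc_icr = b_c + s_c * male_i + w_c * status_i
                   + f_i . L_c + u_ic
                   + [signal c only] d_eff * divstd_i + abar_ic
                   + eps_icr,   eps ~ N(0, noise_sd^2)

with, term by term:

* ``b_c`` — per-compound baseline, Uniform(2, 6) log-units;
* ``s_c, w_c`` — per-compound signed sex and breeding-status loadings,
  N(0, sex_effect^2) and N(0, breeding_effect^2). Different volatiles
  rise or fall with sex and incubation stage rather than shifting in
  lockstep, so no nuisance factor collapses into a single dominant
  chemical axis (a uniform shift would make PC1 collinear with breeding
  status, a regime real profiles do not exhibit);
* ``f_i . L_c + u_ic`` — individual identity: shared latent factors plus
  per-bird-per-compound idiosyncrasy, stable across replicates. These
  dominate the leading principal components, as individual signatures do
  in real feather chemistry;
* ``d_eff * divstd_i`` — diversity channel: the slope (``diversity_effect``,
  defaulting to ``effect_size``) times the bird's standardized both-loci
  functional diversity;
* ``abar_ic`` — dyadic channel: the mean over the bird's four allele
  copies of fixed per-allele contributions. Each contribution is a signed
  per-compound weight (shared across the paralogous loci) times the
  allele's coordinate on the dominant principal axis of the pool's
  functional distance matrix, so functionally close alleles contribute
  similar chemistry — the odour–gene covariance the dyadic analysis is
  built to detect — whether or not any copies are shared exactly.

The recorded peak area is conc x internal-standard area x sample mass,
so standardization downstream recovers conc exactly and ``noise_sd=0``
yields bit-identical standardized replicates. Breeding status is
sample_day - hatch_day (negative during incubation, larger = later);
sampling day is uniform over the incubation span.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .mhc import (DAB1, DAB2, LOCI, Allele, Genotype, _AlleleDistanceCache,
                  genotype_diversity, write_allele_fasta)
from .zscales import STANDARD_RESIDUES

INCUBATION_DAYS = 45


@dataclass
class SimConfig:
    """Study-design and effect parameters of one synthetic cohort."""

    n_per_sex: int = 40
    n_compounds: int = 80
    n_signal_compounds: int = 10
    alleles_per_locus: int = 8
    seq_length: int = 100
    effect_size: float = 0.5
    diversity_effect: float | None = None  # None -> effect_size
    noise_sd: float = 0.3
    sex_effect: float = 0.5
    breeding_effect: float = 0.02
    incubation_span_days: int = INCUBATION_DAYS
    n_replicates: int = 3
    seed: int = 0
    allele_freqs: tuple[float, ...] | None = None  # uniform if None
    pool_structure: str = "gradient"
    max_divergence: float = 0.4
    genotype_coherence: float = 0.5
    n_factors: int = 4
    factor_sd: float = 0.5
    individual_sd: float = 1.0

    def validate(self) -> None:
        for name in ("n_per_sex", "n_compounds", "n_signal_compounds",
                     "alleles_per_locus", "seq_length", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_signal_compounds > self.n_compounds:
            raise ValueError("n_signal_compounds must be <= n_compounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.incubation_span_days < 1:
            raise ValueError("incubation_span_days must be >= 1")
        if self.pool_structure not in ("uniform", "gradient"):
            raise ValueError("pool_structure must be 'uniform' or 'gradient'")
        if not 0 <= self.genotype_coherence <= 1:
            raise ValueError("genotype_coherence must lie in [0, 1]")
        if self.n_factors < 0 or self.factor_sd < 0:
            raise ValueError("n_factors and factor_sd must be >= 0")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")
        if not 0 <= self.max_divergence <= 1:
            raise ValueError("max_divergence must lie in [0, 1]")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if f.size != self.alleles_per_locus or np.any(f < 0) or not np.isclose(f.sum(), 1):
                raise ValueError("allele_freqs must be a length-alleles_per_locus simplex")


@dataclass
class SimulatedStudy:
    """A generated cohort plus the ground truth used to build it."""

    peak_table: pd.DataFrame
    genotype_table: pd.DataFrame
    genotypes: list[Genotype]
    allele_pools: dict[str, list[Allele]]
    truth: dict
    config: SimConfig

    @property
    def compound_names(self) -> list[str]:
        from .chem import compound_columns

        return compound_columns(self.peak_table)


def generate_allele_pool(
    n_alleles: int,
    seq_length: int,
    seed: int,
    locus: str = DAB1,
    structure: str = "uniform",
    max_divergence: float = 0.4,
) -> list[Allele]:
    """Draw ``n_alleles`` distinct amino-acid sequences of one length.

    ``structure='uniform'`` (default) draws sequences iid uniform over
    the 20 standard residues. ``structure='gradient'`` builds a nested
    mutational ladder: allele k carries allele k-1's substitutions plus
    fresh ones, up to a fraction ``max_divergence`` of positions for the
    last allele, so functional distance grows monotonically with rank
    separation and the pool spans a continuum of divergence the way real
    allele series do. Uniform pools are nearly equidistant in descriptor
    space — high-dimensional concentration — which makes every dyadic
    genotype distance about the same and leaves covariance analyses
    nothing to detect, so cohort simulation uses the gradient form.
    """
    if n_alleles < 1 or seq_length < 1:
        raise ValueError("n_alleles and seq_length must be >= 1")
    if float(n_alleles) > 20.0**seq_length:
        raise ValueError(
            f"cannot draw {n_alleles} distinct sequences of length {seq_length}"
        )
    if structure not in ("uniform", "gradient"):
        raise ValueError(f"unknown pool structure {structure!r}")
    rng = np.random.default_rng(seed)
    residues = np.array(list(STANDARD_RESIDUES))
    founder = rng.choice(residues, size=seq_length)
    short = locus.replace("Ocle-", "")
    seen: set[str] = set()
    out: list[Allele] = []
    if structure == "gradient":
        if n_alleles - 1 > seq_length:
            raise ValueError("gradient pool needs seq_length >= n_alleles - 1")
        # nested substitution ladder over a fixed position permutation
        perm = rng.permutation(seq_length)
        alts = np.array([
            str(rng.choice(residues[residues != founder[k]])) for k in range(seq_length)
        ])
        total = max(int(round(max_divergence * seq_length)), n_alleles - 1)
        total = min(total, seq_length)
        seq = founder.copy()
        prev = 0
        for k in range(n_alleles):
            m = max(prev + 1, int(round(total * k / max(n_alleles - 1, 1)))) if k else 0
            for pos in perm[prev:m]:
                seq[pos] = alts[pos]
            prev = max(prev, m)
            out.append(Allele(id=f"{short}*{k + 1:02d}", locus=locus,
                              sequence="".join(seq)))
        return out
    while len(out) < n_alleles:
        seq = "".join(rng.choice(residues, size=seq_length))
        if seq in seen:
            continue
        seen.add(seq)
        out.append(Allele(id=f"{short}*{len(out) + 1:02d}", locus=locus, sequence=seq))
    return out


def _functional_embedding(alleles: list[Allele], max_dim: int = 5) -> np.ndarray:
    """Classical-MDS coordinates of the pool's functional distance matrix.

    Returns an (n_alleles x q) array whose Euclidean geometry reproduces
    the pairwise allele distances (top q <= max_dim positive-eigenvalue
    dimensions), scaled to unit mean squared norm so downstream effect
    sizes are on a fixed scale.
    """
    from .mhc import allele_distance_frame

    d = allele_distance_frame(alleles).to_numpy()
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = lam > max(lam[0], 0) * 1e-10
    q = min(int(keep.sum()), max_dim)
    if q == 0:
        return np.zeros((n, 1))
    coords = vec[:, :q] * np.sqrt(lam[:q])
    # orient each axis along pool order (for ladder pools: divergence
    # order), a sign convention that keeps paralogous loci aligned
    rank = np.arange(n) - (n - 1) / 2.0
    for dim in range(q):
        if coords[:, dim] @ rank < 0:
            coords[:, dim] *= -1.0
    scale = np.sqrt((coords**2).sum(axis=1).mean())
    return coords / (scale if scale > 0 else 1.0)


def generate_cohort(config: SimConfig) -> SimulatedStudy:
    """Generate one cohort under ``config`` (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pools = {
        locus: generate_allele_pool(
            config.alleles_per_locus, config.seq_length,
            seed=int(rng.integers(2**31)), locus=locus,
            structure=config.pool_structure,
            max_divergence=config.max_divergence,
        )
        for locus in LOCI
    }
    freqs = None if config.allele_freqs is None else np.asarray(config.allele_freqs)

    # individuals: females then males, ids F001.., M001..
    n = config.n_per_sex
    ids = [f"F{k + 1:03d}" for k in range(n)] + [f"M{k + 1:03d}" for k in range(n)]
    sexes = ["F"] * n + ["M"] * n

    genotypes: list[Genotype] = []
    span = config.incubation_span_days
    coher = config.genotype_coherence
    n_pool = config.alleles_per_locus
    for ind, sex in zip(ids, sexes):
        alleles = {}
        # copies cluster around one per-individual centre allele: the two
        # class IIB loci sit on one haplotype block and real cohorts carry
        # few, repeated multi-locus genotypes, so within-individual copies
        # are functionally correlated rather than independent draws
        center = int(rng.choice(n_pool, p=freqs))
        jitter_sd = (1.0 - coher) * max(n_pool - 1, 1)
        for locus in LOCI:
            if coher <= 0:
                pick = rng.choice(n_pool, size=2, replace=True, p=freqs)
            else:
                pick = np.clip(np.rint(center + rng.normal(0.0, jitter_sd, size=2)),
                               0, n_pool - 1).astype(int)
            alleles[locus] = (pools[locus][pick[0]], pools[locus][pick[1]])
        hatch = int(rng.integers(span, 2 * span))  # season spread
        days_into = int(rng.integers(0, span + 1))
        sample = hatch - span + days_into
        genotypes.append(Genotype(ind, alleles, sex=sex,
                                  breeding_status=float(sample - hatch),
                                  sample_day=float(sample), hatch_day=float(hatch)))

    # ground-truth chemical structure
    comp_names = [f"c{k + 1:03d}" for k in range(config.n_compounds)]
    signal_idx = np.sort(rng.choice(config.n_compounds, config.n_signal_compounds,
                                    replace=False))
    baselines = rng.uniform(2.0, 6.0, size=config.n_compounds)
    sex_load = rng.normal(0.0, config.sex_effect, size=config.n_compounds) \
        if config.sex_effect > 0 else np.zeros(config.n_compounds)
    breed_load = rng.normal(0.0, config.breeding_effect, size=config.n_compounds) \
        if config.breeding_effect > 0 else np.zeros(config.n_compounds)
    # allele contributions: random mixing of a metric embedding of each
    # locus pool's functional distance matrix, so chemical distance
    # between contributions tracks functional allele distance. Loci are
    # embedded separately — pooling them would make the dominant axis a
    # locus indicator, which cancels in every individual's 2+2 average.
    all_alleles = [a for locus in LOCI for a in pools[locus]]
    contrib: dict[str, np.ndarray] = {}
    # per-compound response to functional divergence: one signed weight
    # per signal compound, shared across the paralogous loci (a
    # compound's response direction is a property of its chemistry, not
    # of the locus), applied to each pool's dominant functional axis
    weights = (rng.choice([-1.0, 1.0], size=config.n_signal_compounds)
               * rng.uniform(0.5, 1.5, size=config.n_signal_compounds))
    for locus in LOCI:
        emb1 = _functional_embedding(pools[locus], max_dim=1)[:, 0]
        for k, a in enumerate(pools[locus]):
            contrib[a.id] = config.effect_size * emb1[k] * weights

    cache = _AlleleDistanceCache(all_alleles)
    div = np.array([genotype_diversity(g, "both", "mean", _cache=cache)
                    for g in genotypes])
    # diversity enters standardized: the slope is per s.d. of diversity
    div_sd = div.std(ddof=0)
    div_std = (div - div.mean()) / (div_sd if div_sd > 0 else 1.0)
    div_effect = (config.effect_size if config.diversity_effect is None
                  else config.diversity_effect)

    n_ind, n_rep, p = len(ids), config.n_replicates, config.n_compounds
    mu = np.tile(baselines, (n_ind, 1))
    male = np.array([s == "M" for s in sexes], dtype=float)
    status = np.array([g.breeding_status for g in genotypes])
    mu += male[:, None] * sex_load[None, :]
    mu += status[:, None] * breed_load[None, :]
    # latent individual-identity factors: birds carry distinctive multi-
    # compound signatures (diet, microbiome, identity) unrelated to the
    # MHC; these dominate the leading chemical axes as in real profiles
    if config.n_factors > 0 and config.factor_sd > 0:
        fac_load = rng.normal(0.0, config.factor_sd,
                              size=(p, config.n_factors))
        fac_scores = rng.normal(0.0, 1.0, size=(n_ind, config.n_factors))
        mu += fac_scores @ fac_load.T
    # per-bird, per-compound idiosyncrasy (stable across replicates):
    # the residual individuality of odour profiles beyond shared factors
    if config.individual_sd > 0:
        mu += rng.normal(0.0, config.individual_sd, size=(n_ind, p))
    abar = np.array([
        np.mean([contrib[a.id] for a in g.copies(LOCI)], axis=0) for g in genotypes
    ])
    mu[:, signal_idx] += div_effect * div_std[:, None] + abar

    noise = rng.normal(0.0, config.noise_sd, size=(n_ind, n_rep, p)) \
        if config.noise_sd > 0 else np.zeros((n_ind, n_rep, p))
    conc = np.exp(mu[:, None, :] + noise)

    is_area = np.exp(rng.normal(11.5, 0.1, size=(n_ind, n_rep)))
    mass = np.exp(rng.normal(np.log(0.004), 0.1, size=(n_ind, n_rep)))
    areas = conc * (is_area * mass)[:, :, None]

    rows = []
    for i, ind in enumerate(ids):
        for r in range(n_rep):
            rows.append({"individual": ind, "replicate": r + 1,
                         "sample_mass": mass[i, r],
                         "internal_standard_area": is_area[i, r],
                         **dict(zip(comp_names, areas[i, r]))})
    peak_table = pd.DataFrame(rows)

    genotype_table = pd.DataFrame({
        "individual": ids,
        "sex": sexes,
        "sample_day": [g.sample_day for g in genotypes],
        "hatch_day": [g.hatch_day for g in genotypes],
        "DAB1_1": [g.alleles[DAB1][0].id for g in genotypes],
        "DAB1_2": [g.alleles[DAB1][1].id for g in genotypes],
        "DAB2_1": [g.alleles[DAB2][0].id for g in genotypes],
        "DAB2_2": [g.alleles[DAB2][1].id for g in genotypes],
    })

    truth = {
        "signal_compounds": [comp_names[k] for k in signal_idx],
        "signal_indices": [int(k) for k in signal_idx],
        "effect_size": config.effect_size,
        "noise_sd": config.noise_sd,
        "sex_effect": config.sex_effect,
        "breeding_effect": config.breeding_effect,
        "sex_loadings": [float(v) for v in sex_load],
        "breeding_loadings": [float(v) for v in breed_load],
        "allele_contributions": {aid: [float(v) for v in vec]
                                 for aid, vec in contrib.items()},
        "diversity": {ind: float(d) for ind, d in zip(ids, div)},
    }
    return SimulatedStudy(peak_table, genotype_table, genotypes, pools, truth, config)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write peak table / genotype table (TSV), allele FASTA, truth and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.peak_table.to_csv(out / "peak_table.tsv", sep="\t", index=False,
                            float_format="%.10g")
    study.genotype_table.to_csv(out / "genotype_table.tsv", sep="\t", index=False,
                                float_format="%.10g")
    write_allele_fasta([a for locus in LOCI for a in study.allele_pools[locus]],
                       out / "alleles.faa")
    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
    cfg = asdict(study.config)
    if cfg["allele_freqs"] is not None:
        cfg["allele_freqs"] = list(cfg["allele_freqs"])
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
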