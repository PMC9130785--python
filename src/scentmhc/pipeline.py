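"""End-to-end orchestration: data -> chemistry -> genetics -> reports.

``run_pipeline`` takes a :class:`PipelineConfig` (or its YAML form),
either simulates a cohort or ingests peak-table / genotype / allele
files, and writes a report bundle:

* ``profiles.tsv``, ``pca_*.tsv`` — per-bird chemistry and PCA report;
* ``models.tsv`` — the six interaction models ({PC1, PC2} x {DAB1,
  DAB2, both}): per-term estimates, s.e., CI, Type III p;
* ``dyadic_tests.tsv`` — the nine-test family ({FF, MM, MF} x {DAB1,
  DAB2, both}), each row reporting both chemical components with the
  other component controlled, Bonferroni threshold attached;
* ``bioenv.tsv`` — BIO-ENV best subsets for the within-sex groups with
  a significant positive dyadic correlation (none under a null run);
* ``manifest.json`` — config, seeds and the analysis decisions in
  effect.

Outputs are a pure function of config + seeds: rerunning a manifest
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioenv import bioenv, bioenv_greedy, prefilter_compounds
from .chem import (aggregate_individuals, pc_distance_matrices, read_peak_table,
                   retain_components, run_pca, write_pca_report)
from .dyadic import bonferroni_alpha, partial_mantel, partial_spearman_rect
from .dyads import split_by_sex
from .mhc import (build_mhc_matrices, genotype_diversity, read_allele_fasta,
                  read_genotype_table)
from .models import fit_interaction_model
from .simulate import SimConfig, generate_cohort, write_study

logger = logging.getLogger(__name__)

LOCUS_MODES = ("DAB1", "DAB2", "both")
FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    out_dir: str = "scentmhc_out"
    # either a simulation config ...
    sim: SimConfig | None = None
    # ... or paths to observed inputs
    peak_table: str | None = None
    genotype_table: str | None = None
    allele_fasta: str | None = None
    allele_alphabet: str = "aa"

    pca_scale: bool = True
    n_components_override: int | None = 2
    dyad_rule: str = "max"
    rect_restricted: bool = False
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    model_family_size: int = 6
    mantel_family_size: int = 9
    bioenv_k_max: int = 6
    bioenv_correlation: str = "mantel_pearson"
    bioenv_max_compounds: int = 25
    bioenv_greedy: bool = False
    write_inputs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")  # location is not part of the analysis
        if self.sim is not None and d["sim"].get("allele_freqs") is not None:
            d["sim"]["allele_freqs"] = list(d["sim"]["allele_freqs"])
        return d


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        study = generate_cohort(config.sim)
        return study.peak_table, study.genotypes, study
    if not (config.peak_table and config.genotype_table and config.allele_fasta):
        raise ValueError("config needs either `sim` or all three input paths")
    peaks = read_peak_table(config.peak_table)
    alleles = read_allele_fasta(config.allele_fasta, alphabet=config.allele_alphabet)
    genotypes = read_genotype_table(config.genotype_table, alleles)
    return peaks, genotypes, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a small in-memory report index."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks, genotypes, study = _load_inputs(config)
    if study is not None and config.write_inputs:
        write_study(study, out / "inputs")

    # --- chemistry ---------------------------------------------------
    logger.info("stage chem: %d replicate rows", len(peaks))
    profiles = aggregate_individuals(peaks)
    profiles.to_csv(out / "profiles.tsv", sep="\t", index_label="individual",
                    float_format=FLOAT_FMT)
    pcs = run_pca(profiles, scale=config.pca_scale)
    n_keep = retain_components(
        pcs.eigenvalues, n_samples=len(profiles),
        n_variables=pcs.loadings.shape[0],
        override=config.n_components_override, seed=config.seed,
    )
    n_keep = max(n_keep, 2)  # the dyadic family needs two components
    write_pca_report(pcs, out, n_components=n_keep)

    by_id = {g.individual: g for g in genotypes}
    missing = [i for i in profiles.index if i not in by_id]
    if missing:
        raise ValueError(f"stage chem: individuals without genotype: {missing}")
    order = [by_id[i] for i in profiles.index]
    sexes = [g.sex for g in order]
    status = np.array([g.breeding_status for g in order])

    # --- individual-level models ------------------------------------
    logger.info("stage models: 6 interaction models")
    div_cols = {m: [genotype_diversity(g, m, "mean") for g in order] for m in LOCUS_MODES}
    data = pd.DataFrame({
        "individual": list(profiles.index), "sex": sexes, "breeding_status": status,
        "PC1": pcs.scores["PC1"].to_numpy(), "PC2": pcs.scores["PC2"].to_numpy(),
        **{f"div_{m}": v for m, v in div_cols.items()},
    })
    alpha_models = bonferroni_alpha(config.alpha, config.model_family_size)
    model_rows = []
    for response in ("PC1", "PC2"):
        for mode in LOCUS_MODES:
            res = fit_interaction_model(data, response, f"div_{mode}")
            tab = res.term_table()
            tab.insert(0, "response", response)
            tab.insert(1, "diversity", mode)
            tab["adj_r2"] = res.rsquared_adj
            tab["F"] = res.fvalue
            tab["df"] = f"{res.df_model},{res.df_resid}"
            tab["adjusted_alpha"] = alpha_models
            model_rows.append(tab)
    pd.concat(model_rows, ignore_index=True).to_csv(
        out / "models.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # --- dyadic tests ------------------------------------------------
    logger.info("stage dyadic: %d-test family, n_perm=%d",
                config.mantel_family_size, config.n_perm)
    alpha_mantel = bonferroni_alpha(config.alpha, config.mantel_family_size)
    pc_mats = {pc: pc_distance_matrices(pcs, sexes, pc) for pc in ("PC1", "PC2")}
    status_mats = split_by_sex(status, list(profiles.index), sexes)
    rng = np.random.default_rng(config.seed)
    dyad_rows = []
    sig_targets = []
    for mode in LOCUS_MODES:
        mhc_mats = build_mhc_matrices(genotypes, mode, config.dyad_rule)
        for group in ("MM", "FF", "MF"):
            row = {"group": group, "genetic_distance": mode,
                   "n_dyads": mhc_mats[group].n_dyads,
                   "test": "partial Spearman" if group == "MF" else "partial Mantel",
                   "adjusted_alpha": alpha_mantel}
            for pc, other in (("PC1", "PC2"), ("PC2", "PC1")):
                covs = [pc_mats[other][group], status_mats[group]]
                seed_t = int(rng.integers(2**31))
                if group == "MF":
                    res = partial_spearman_rect(
                        pc_mats[pc][group], mhc_mats[group], covs,
                        n_perm=config.n_perm, seed=seed_t,
                        restricted=config.rect_restricted)
                else:
                    res = partial_mantel(pc_mats[pc][group], mhc_mats[group], covs,
                                         n_perm=config.n_perm, seed=seed_t)
                row[f"{pc}_stat"] = res.statistic
                row[f"{pc}_p"] = res.p_value
                row[f"{pc}_seed"] = seed_t
                if (group in ("FF", "MM") and res.statistic > 0
                        and res.p_value < alpha_mantel):
                    sig_targets.append((group, mode, mhc_mats[group]))
            dyad_rows.append(row)
    dyadic = pd.DataFrame(dyad_rows)
    dyadic.to_csv(out / "dyadic_tests.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # --- BIO-ENV on significant positive within-sex correlations -----
    logger.info("stage bioenv: %d target(s)", len(sig_targets))
    bio_rows = []
    seen = set()
    for group, mode, target in sig_targets:
        if (group, mode) in seen:
            continue
        seen.add((group, mode))
        members = list(target.row_ids)
        prof_g = profiles.loc[members]
        prefiltered = (prof_g.shape[1] > config.bioenv_max_compounds
                       and not config.bioenv_greedy)
        if prefiltered:
            keep = prefilter_compounds(prof_g, target, config.bioenv_max_compounds)
            logger.warning("bioenv %s/%s: pre-filtered %d -> %d compounds",
                           group, mode, prof_g.shape[1], len(keep))
            prof_g = prof_g[keep]
        search = bioenv_greedy if config.bioenv_greedy else bioenv
        res = search(prof_g, target, k_max=config.bioenv_k_max,
                     correlation=config.bioenv_correlation)
        bio_rows.append({
            "group": group, "genetic_distance": mode,
            "correlation": res.best_correlation, "k": len(res.best_subset),
            "compounds": ", ".join(res.best_subset),
            "correlation_type": res.correlation,
            "prefiltered": prefiltered,
        })
    pd.DataFrame(bio_rows, columns=["group", "genetic_distance", "correlation",
                                    "k", "compounds", "correlation_type",
                                    "prefiltered"]).to_csv(
        out / "bioenv.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # --- manifest ----------------------------------------------------
    manifest = {
        "scentmhc_version": __version__,
        "config": config.to_jsonable(),
        "n_individuals": len(profiles),
        "n_compounds": profiles.shape[1],
        "n_components_retained": int(n_keep),
        "variance_fraction_retained": float(pcs.variance_fraction[:n_keep].sum()),
        "decisions": {
            "pca_scale": config.pca_scale,
            "dyad_rule": config.dyad_rule,
            "rect_null": "restricted-row" if config.rect_restricted else "dyad-entry",
            "bioenv_correlation": config.bioenv_correlation,
            "order_of_operations": "standardize -> average -> log(X+1)",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return {"out_dir": str(out), "manifest": manifest, "dyadic": dyadic,
            "n_significant_positive": len(sig_targets)}
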