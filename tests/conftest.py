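import pandas as pd
import pytest

from scentmhc.mhc import DAB1, DAB2, Allele, Genotype
from scentmhc.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_study():
    """A small deterministic cohort shared across read-only tests."""
    cfg = SimConfig(n_per_sex=10, n_compounds=12, n_signal_compounds=3,
                    alleles_per_locus=4, seq_length=30, seed=12345)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_alleles():
    """Four short alleles (two per locus) with hand-checkable distances."""
    return {
        "a": Allele("DAB1*a", DAB1, "ACDEF"),
        "b": Allele("DAB1*b", DAB1, "ACDEW"),
        "c": Allele("DAB2*c", DAB2, "GHIKL"),
        "d": Allele("DAB2*d", DAB2, "GHIKM"),
    }


@pytest.fixture()
def toy_genotype(toy_alleles):
    t = toy_alleles
    return Genotype("bird1", {DAB1: (t["a"], t["b"]), DAB2: (t["c"], t["d"])},
                    sex="F", breeding_status=-10.0)


def make_peak_table(values, is_areas=None, masses=None):
    """Build a replicate-level peak table from a dict
    {(individual, replicate): compound-vector}."""
    rows = []
    for k, ((ind, rep), vec) in enumerate(values.items()):
        rows.append({
            "individual": ind, "replicate": rep,
            "sample_mass": 1.0 if masses is None else masses[k],
            "internal_standard_area": 1.0 if is_areas is None else is_areas[k],
            **{f"c{j + 1:02d}": v for j, v in enumerate(vec)},
        })
    return pd.DataFrame(rows)
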