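"""Functional distance machinery: residues, alleles, genotypes, dyads."""

import itertools

import numpy as np
import pytest

from scentmhc.mhc import (DAB1, DAB2, Allele, Genotype, aa_distance,
                          aa_distance_matrix, allele_distance,
                          allele_distance_frame, build_mhc_matrices,
                          dyad_mhc_distance, genotype_diversity,
                          heterozygosity_correlation, mhc_heterozygosity,
                          read_allele_fasta, read_genotype_table,
                          translate_cds, write_allele_fasta)
from scentmhc.simulate import SimConfig, generate_cohort
from scentmhc.zscales import (STANDARD_RESIDUES, validate_descriptor_table,
                              z_descriptor_table)


class TestZTable:
    def test_shape_and_finiteness(self):
        tab = z_descriptor_table()
        assert tab.shape == (20, 5)
        assert list(tab.columns) == ["z1", "z2", "z3", "z4", "z5"]
        assert np.isfinite(tab.to_numpy()).all()
        assert set(tab.index) == set(STANDARD_RESIDUES)

    def test_validation_rejects_missing_residue(self):
        tab = z_descriptor_table().drop(index="A")
        with pytest.raises(ValueError, match="20 standard residues"):
            validate_descriptor_table(tab)

    def test_validation_rejects_nan(self):
        tab = z_descriptor_table()
        tab.loc["A", "z3"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            validate_descriptor_table(tab)


class TestAaDistance:
    def test_identity_all_residues(self):
        for r in STANDARD_RESIDUES:
            assert aa_distance(r, r) == 0.0

    def test_symmetry_all_400_pairs(self):
        d = aa_distance_matrix().to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(d >= 0)

    def test_matches_brute_force_sum_of_squares(self):
        tab = z_descriptor_table()
        rng = np.random.default_rng(1)
        for a, b in rng.choice(list(STANDARD_RESIDUES), size=(20, 2)):
            expected = sum((tab.loc[a, f"z{k}"] - tab.loc[b, f"z{k}"]) ** 2
                           for k in range(1, 6)) ** 0.5
            assert abs(aa_distance(a, b) - expected) < 1e-12

    def test_triangle_inequality_all_triples(self):
        d = aa_distance_matrix().to_numpy()
        # d(a,c) <= d(a,b) + d(b,c) over all 20^3 triples, vectorized
        lhs = d[:, None, :]
        rhs = d[:, :, None] + d[None, :, :]
        assert np.all(lhs <= rhs + 1e-12)

    def test_unknown_symbol_raises(self):
        with pytest.raises(ValueError, match="'X'"):
            aa_distance("A", "X")

    def test_homogeneity_in_descriptor_scale(self):
        tab = z_descriptor_table()
        scaled = aa_distance_matrix(tab * -2.5).to_numpy()
        base = aa_distance_matrix(tab).to_numpy()
        assert np.allclose(scaled, 2.5 * base)


class TestAlleleDistance:
    def test_identical_sequences(self, toy_alleles):
        assert allele_distance(toy_alleles["a"], toy_alleles["a"]) == 0.0

    def test_single_differing_position(self, toy_alleles):
        # ACDEF vs ACDEW differ only at the last of 5 positions
        expected = aa_distance("F", "W") / 5
        assert abs(allele_distance(toy_alleles["a"], toy_alleles["b"]) - expected) < 1e-12

    def test_matches_positionwise_loop(self):
        rng = np.random.default_rng(2)
        res = list(STANDARD_RESIDUES)
        s1 = "".join(rng.choice(res, 30))
        s2 = "".join(rng.choice(res, 30))
        expected = np.mean([aa_distance(x, y) for x, y in zip(s1, s2)])
        assert abs(allele_distance(s1, s2) - expected) < 1e-12

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            allele_distance("ACD", "ACDE")

    def test_position_mask_restricts_average(self, toy_alleles):
        a, b = toy_alleles["a"], toy_alleles["b"]
        assert allele_distance(a, b, position_mask=[0, 1]) == 0.0
        assert abs(allele_distance(a, b, position_mask=[4])
                   - aa_distance("F", "W")) < 1e-12

    def test_distance_frame_symmetric_zero_diagonal(self, toy_alleles):
        frame = allele_distance_frame(list(toy_alleles.values()))
        arr = frame.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)


class TestGenotypeDiversity:
    def test_homozygote_is_zero(self, toy_alleles):
        t = toy_alleles
        g = Genotype("h", {DAB1: (t["a"], t["a"]), DAB2: (t["c"], t["c"])})
        assert genotype_diversity(g, "DAB1") == 0.0

    def test_heterozygote_equals_allele_distance(self, toy_genotype, toy_alleles):
        d = allele_distance(toy_alleles["c"], toy_alleles["d"])
        assert abs(genotype_diversity(toy_genotype, "DAB2") - d) < 1e-12

    def test_both_loci_mean_over_six_pairs(self, toy_alleles):
        t = toy_alleles
        g = Genotype("g", {DAB1: (t["a"], t["a"]), DAB2: (t["b"], t["b"])})
        # copies {a,a,b,b}: six unordered pairs, four of them (a,b)
        d = allele_distance(t["a"], t["b"])
        expected = 4 * d / 6
        assert abs(genotype_diversity(g, "both", "mean") - expected) < 1e-12
        assert abs(genotype_diversity(g, "both", "max") - d) < 1e-12

    def test_exhaustive_pair_oracle(self, toy_genotype):
        copies = toy_genotype.copies([DAB1, DAB2])
        dists = [allele_distance(x, y) for x, y in itertools.combinations(copies, 2)]
        assert abs(genotype_diversity(toy_genotype, "both", "mean") - np.mean(dists)) < 1e-12

    def test_zero_iff_all_copies_identical(self, toy_alleles):
        t = toy_alleles
        same = Allele("DAB2*a2", DAB2, t["a"].sequence)
        g = Genotype("g", {DAB1: (t["a"], t["a"]), DAB2: (same, same)})
        assert genotype_diversity(g, "both") == 0.0
        g2 = Genotype("g2", {DAB1: (t["a"], t["a"]), DAB2: (same, t["c"])})
        assert genotype_diversity(g2, "both") > 0.0

    def test_missing_locus_raises(self, toy_alleles):
        t = toy_alleles
        g = Genotype("g", {DAB1: (t["a"], t["b"])})
        with pytest.raises(KeyError, match="missing locus"):
            genotype_diversity(g, "both")


class TestDyadDistance:
    def test_identical_homozygotes_zero(self, toy_alleles):
        t = toy_alleles
        g1 = Genotype("x", {DAB1: (t["a"], t["a"]), DAB2: (t["c"], t["c"])})
        g2 = Genotype("y", {DAB1: (t["a"], t["a"]), DAB2: (t["c"], t["c"])})
        assert dyad_mhc_distance(g1, g2, "both") == 0.0

    def test_single_cross_pair(self, toy_alleles):
        t = toy_alleles
        g1 = Genotype("x", {DAB1: (t["a"], t["a"])})
        g2 = Genotype("y", {DAB1: (t["b"], t["b"])})
        assert abs(dyad_mhc_distance(g1, g2, "DAB1")
                   - allele_distance(t["a"], t["b"])) < 1e-12

    def test_max_over_four_cross_pairs(self, toy_alleles):
        t = toy_alleles
        g1 = Genotype("x", {DAB1: (t["a"], t["b"])})
        g2 = Genotype("y", {DAB1: (t["c"], t["d"])})
        cross = [allele_distance(x, y) for x in (t["a"], t["b"])
                 for y in (t["c"], t["d"])]
        assert abs(dyad_mhc_distance(g1, g2, "DAB1", "max") - max(cross)) < 1e-12
        assert abs(dyad_mhc_distance(g1, g2, "DAB1", "mean") - np.mean(cross)) < 1e-12

    def test_symmetry(self, toy_alleles):
        t = toy_alleles
        g1 = Genotype("x", {DAB1: (t["a"], t["b"]), DAB2: (t["c"], t["c"])})
        g2 = Genotype("y", {DAB1: (t["b"], t["b"]), DAB2: (t["d"], t["c"])})
        assert dyad_mhc_distance(g1, g2, "both") == dyad_mhc_distance(g2, g1, "both")


class TestBuildMatrices:
    def test_cohort_of_clones_gives_zero_matrices(self, toy_alleles):
        t = toy_alleles
        genos = [Genotype(f"i{k}", {DAB1: (t["a"], t["a"]), DAB2: (t["c"], t["c"])},
                          sex="F" if k < 3 else "M") for k in range(6)]
        mats = build_mhc_matrices(genos, "both")
        for m in mats.values():
            assert np.allclose(m.values, 0)

    def test_dyad_counts_for_thirty_per_sex(self):
        cfg = SimConfig(n_per_sex=30, n_compounds=5, n_signal_compounds=1,
                        alleles_per_locus=4, seq_length=20, seed=7)
        study = generate_cohort(cfg)
        mats = build_mhc_matrices(study.genotypes, "DAB1")
        assert mats["FF"].n_dyads == 435
        assert mats["MM"].n_dyads == 435
        assert mats["MF"].n_dyads == 900

    def test_three_individual_toy_vs_pairwise_oracle(self, toy_alleles):
        t = toy_alleles
        genos = [
            Genotype("f1", {DAB1: (t["a"], t["b"]), DAB2: (t["c"], t["c"])}, sex="F"),
            Genotype("f2", {DAB1: (t["b"], t["b"]), DAB2: (t["c"], t["d"])}, sex="F"),
            Genotype("m1", {DAB1: (t["a"], t["a"]), DAB2: (t["d"], t["d"])}, sex="M"),
        ]
        mats = build_mhc_matrices(genos, "both")
        assert mats["FF"].values[0, 1] == pytest.approx(
            dyad_mhc_distance(genos[0], genos[1], "both"))
        assert mats["MF"].values[0, 0] == pytest.approx(
            dyad_mhc_distance(genos[2], genos[0], "both"))
        assert mats["MF"].values[0, 1] == pytest.approx(
            dyad_mhc_distance(genos[2], genos[1], "both"))

    def test_unknown_sex_raises(self, toy_alleles):
        t = toy_alleles
        g = Genotype("u", {DAB1: (t["a"], t["a"]), DAB2: (t["c"], t["c"])}, sex="?")
        with pytest.raises(ValueError, match="unknown sex"):
            build_mhc_matrices([g], "both")


class TestHeterozygosity:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert heterozygosity_correlation(x, x) == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        y = np.array([0.21, 0.33, 0.25, 0.19, 0.30])
        num = np.mean((x - x.mean()) * (y - y.mean()))
        expected = num / (x.std() * y.std())
        assert heterozygosity_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported(self):
        with pytest.raises(ValueError, match="zero variance"):
            heterozygosity_correlation([1, 1, 1], [0.1, 0.2, 0.3])

    def test_indicator_and_functional_modes(self, toy_genotype, toy_alleles):
        assert mhc_heterozygosity(toy_genotype, DAB1) == 1.0
        f = mhc_heterozygosity(toy_genotype, DAB1, mode="functional")
        assert f == pytest.approx(allele_distance(toy_alleles["a"], toy_alleles["b"]))


class TestSequenceInput:
    def test_translate_standard_code(self):
        assert translate_cds("ATGGCCTGG") == "MAW"
        assert translate_cds("XATGGCC", frame=1) == "MA"

    def test_premature_stop_raises(self):
        with pytest.raises(ValueError, match="stop codon"):
            translate_cds("ATGTAAGCC")

    def test_fasta_roundtrip_and_genotype_table(self, tmp_path, small_study):
        from scentmhc.simulate import write_study

        write_study(small_study, tmp_path)
        alleles = read_allele_fasta(tmp_path / "alleles.faa")
        assert len(alleles) == 2 * small_study.config.alleles_per_locus
        genos = read_genotype_table(tmp_path / "genotype_table.tsv", alleles)
        assert len(genos) == 2 * small_study.config.n_per_sex
        # rebuilt genotypes carry the same functional diversity
        for g_new, g_old in zip(genos, small_study.genotypes):
            assert g_new.individual == g_old.individual
            assert genotype_diversity(g_new, "both") == pytest.approx(
                genotype_diversity(g_old, "both"))
            assert g_new.breeding_status == pytest.approx(g_old.breeding_status)

    def test_nonstandard_residue_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-standard residue"):
            Allele("bad", DAB1, "ACDX")
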