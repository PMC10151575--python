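"""Relationship matrices, window assignment and genotype I/O."""

import numpy as np
import pandas as pd
import pytest

from sowpop.genotypes import (
    GenotypeMatrix,
    Pedigree,
    assign_windows,
    genomic_relationship,
    pedigree_relationship,
    read_dose_csv,
    read_plink,
    write_dose_csv,
    write_plink,
)
from sowpop.synthetic import SimulationScenario, gene_drop_genotypes, simulate_genotypes


class TestGenomicRelationship:
    def test_matches_brute_force_on_fixture(self, tiny_genotypes):
        G = genomic_relationship(tiny_genotypes)
        M = np.asarray(tiny_genotypes.counts, dtype=float)
        p = M.mean(axis=0) / 2.0
        W = M - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(G.values, expected, atol=1e-12)

    def test_identical_heterozygous_individuals(self):
        # two identical all-heterozygous individuals at p = 0.5: centred rows
        # are zero, so self- and cross-relationship coincide
        m = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [0, 100]})
        geno = GenotypeMatrix(["x", "y"], np.array([[1, 1], [1, 1]]), m)
        G = genomic_relationship(geno)
        assert G.values[0, 0] == pytest.approx(G.values[0, 1], abs=1e-12)
        geno2 = GenotypeMatrix(["x", "y", "z"], np.array([[1, 1], [1, 1], [0, 2]]), m)
        G2 = genomic_relationship(geno2)
        assert G2.values[0, 0] == pytest.approx(G2.values[0, 1], abs=1e-12)

    def test_monomorphic_only_error(self):
        m = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [0, 100]})
        geno = GenotypeMatrix(["x", "y"], np.array([[2, 0], [2, 0]]), m)
        with pytest.raises(ValueError, match="no informative markers"):
            genomic_relationship(geno)

    def test_marker_permutation_invariance(self, tiny_genotypes):
        G1 = genomic_relationship(tiny_genotypes)
        perm = [3, 0, 2, 1]
        shuffled = GenotypeMatrix(
            list(tiny_genotypes.ids),
            tiny_genotypes.counts[:, perm],
            pd.DataFrame(
                {
                    "marker": [f"p{i}" for i in range(4)],
                    "chrom": ["1"] * 4,
                    "bp": [0, 10, 20, 30],
                }
            ),
        )
        G2 = genomic_relationship(shuffled)
        assert np.allclose(G1.values, G2.values, atol=1e-12)

    def test_unrelated_cohort_off_diagonal_near_zero(self):
        scen = SimulationScenario(n_sows=200, n_markers=5000, ld_rho=0.0, seed=5)
        geno = simulate_genotypes(scen)
        G = genomic_relationship(geno)
        off = G.values[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_mean_imputation(self):
        m = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [0, 100]})
        geno = GenotypeMatrix(["x", "y", "z"], np.array([[0, -1], [1, 2], [2, 0]]), m)
        imp = geno.impute_missing()
        assert imp.counts[0, 1] == pytest.approx(1.0)  # mean of 2 and 0


class TestPedigreeRelationship:
    def test_founders_identity(self):
        A = pedigree_relationship(Pedigree([("f1", None, None), ("f2", None, None)]))
        assert np.allclose(A.values, np.eye(2))

    def test_trio(self):
        ped = Pedigree([("s", None, None), ("d", None, None), ("o", "s", "d")])
        A = pedigree_relationship(ped)
        i = {x: k for k, x in enumerate(A.ids)}
        assert A.values[i["o"], i["o"]] == pytest.approx(1.0)
        assert A.values[i["s"], i["o"]] == pytest.approx(0.5)
        assert A.values[i["s"], i["d"]] == pytest.approx(0.0)

    def test_full_sibs_and_inbred_offspring(self):
        ped = Pedigree(
            [
                ("s", None, None),
                ("d", None, None),
                ("c1", "s", "d"),
                ("c2", "s", "d"),
                ("x", "c1", "c2"),
            ]
        )
        A = pedigree_relationship(ped)
        i = {x: k for k, x in enumerate(A.ids)}
        assert A.values[i["c1"], i["c2"]] == pytest.approx(0.5)
        assert A.values[i["x"], i["x"]] == pytest.approx(1.25)

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree([("a", "b", None), ("b", "a", None)])

    def test_gene_dropping_g_approaches_a(self):
        rng = np.random.default_rng(3)
        trips = [(f"f{i}", None, None) for i in range(20)]
        for i in range(60):
            s = f"f{rng.integers(0, 10)}"
            d = f"f{10 + rng.integers(0, 10)}"
            trips.append((f"kid{i}", s, d))
        ped = Pedigree(trips)
        A = pedigree_relationship(ped).values
        errs = []
        for p in (500, 5000):
            geno = gene_drop_genotypes(ped, n_markers=p, seed=7)
            G = genomic_relationship(geno).values
            errs.append(np.abs(G - A).mean())
        assert errs[1] < errs[0]


class TestWindows:
    def test_boundary_half_open(self):
        m = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [999_999, 1_000_000]}
        )
        wm = assign_windows(m)
        assert wm.windows == [("1", 0), ("1", 1)]

    def test_mb_labelling(self):
        m = pd.DataFrame({"marker": ["a"], "chrom": ["14"], "bp": [8_500_000]})
        wm = assign_windows(m)
        assert wm.windows == [("14", 8)]

    def test_partition_and_counts(self):
        bp = np.arange(100) * 100_000  # 100 markers over 10 Mb
        m = pd.DataFrame({"marker": [f"m{i}" for i in range(100)], "chrom": "1", "bp": bp})
        wm = assign_windows(m)
        assert len(wm.windows) == 10
        sizes = [len(wm.marker_indices[w]) for w in wm.windows]
        assert sizes == [10] * 10
        assert sum(sizes) == 100
        assert wm.n_genome_windows == 10

    def test_negative_position_error(self):
        m = pd.DataFrame({"marker": ["a"], "chrom": ["1"], "bp": [-5]})
        with pytest.raises(ValueError, match="negative"):
            assign_windows(m)


class TestIO:
    def test_plink_roundtrip(self, tmp_path):
        scen = SimulationScenario(n_sows=25, n_markers=37, n_chromosomes=2, seed=9)
        geno = simulate_genotypes(scen)
        write_plink(geno, tmp_path / "g")
        back = read_plink(tmp_path / "g")
        assert back.ids == geno.ids
        assert np.array_equal(back.counts, geno.counts)
        assert np.array_equal(back.map["bp"], geno.map["bp"])

    def test_bed_bit_pattern_oracle(self, tmp_path):
        # 3 samples, 1 marker, doses (2, 1, 0) and a second marker (0, -1, 2).
        # SNP-major codes: dose2=00, dose1=10, dose0=11, missing=01; packed
        # LSB-first: marker1 byte = 00|11|10|00 -> 0b00111000; marker2:
        # 11,01,00 -> 0b00000111 with pad 00.
        m = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [0, 10]})
        geno = GenotypeMatrix(
            ["i1", "i2", "i3"], np.array([[2, 0], [1, -1], [0, 2]]), m
        )
        write_plink(geno, tmp_path / "g")
        raw = (tmp_path / "g.bed").read_bytes()
        assert raw[:3] == bytes([0x6C, 0x1B, 0x01])
        assert raw[3] == 0b00111000
        assert raw[4] == 0b00000111
        back = read_plink(tmp_path / "g")
        assert np.array_equal(back.counts, geno.counts)

    def test_bad_magic(self, tmp_path):
        (tmp_path / "bad.bed").write_bytes(b"\x00\x00\x00")
        (tmp_path / "bad.bim").write_text("1\tm\t0\t1\tA\tB\n")
        (tmp_path / "bad.fam").write_text("i i 0 0 2 -9\n")
        with pytest.raises(ValueError, match="magic"):
            read_plink(tmp_path / "bad")

    def test_unsorted_bim_error(self, tmp_path):
        m = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "bp": [10, 0]})
        with pytest.raises(ValueError, match="increasing"):
            GenotypeMatrix(["i"], np.array([[1, 1]]), m)

    def test_dose_csv_roundtrip(self, tiny_genotypes, tmp_path):
        write_dose_csv(tiny_genotypes, tmp_path / "d.csv", tmp_path / "m.csv")
        back = read_dose_csv(tmp_path / "d.csv", tmp_path / "m.csv")
        assert back.ids == tiny_genotypes.ids
        assert np.array_equal(back.counts, tiny_genotypes.counts)
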