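import numpy as np
import pytest

from antcolonykin import geno_io
from antcolonykin.geno_io import (FilterSettings, apply_filters,
                                  filter_individuals, filter_loci,
                                  observed_heterozygosity, read_genotypes,
                                  read_tsv, read_vcf, write_tsv, write_vcf)
from antcolonykin.matrix import MISSING, GenotypeMatrix
from antcolonykin.syndata import (ColonyDesign, apply_observation_noise,
                                  simulate_colonies)
from tests.conftest import make_matrix


@pytest.fixture
def noisy_matrix(panel300):
    design = ColonyDesign(n_trees=2, workers_per_tree=4, queens_per_tree=2,
                          seed=21)
    G, _ = simulate_colonies(design, panel300)
    G.caste[0] = "queen"
    G.excluded[0] = True
    return apply_observation_noise(G, 0.0, 0.0, 0.2, seed=22)


class TestRoundTrips:
    def test_tsv_round_trip(self, tmp_path, noisy_matrix):
        path = tmp_path / "g.tsv"
        write_tsv(noisy_matrix, path)
        assert read_tsv(path).equals(noisy_matrix)

    def test_vcf_round_trip(self, tmp_path, noisy_matrix):
        path = tmp_path / "g.vcf"
        write_vcf(noisy_matrix, path)
        assert read_vcf(path).equals(noisy_matrix)

    def test_format_dispatch(self, tmp_path, noisy_matrix):
        for name in ("g.vcf", "g.tsv"):
            geno_io.write_genotypes(noisy_matrix, tmp_path / name)
            assert read_genotypes(tmp_path / name).equals(noisy_matrix)

    def test_empty_tsv_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("id\tspecies\ttree\tcaste\texcluded\tl0\n")
        with pytest.raises(ValueError, match="no individuals"):
            read_tsv(path)

    def test_malformed_genotype_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "id\tspecies\ttree\tcaste\texcluded\tl0\n"
            "i0\tsp\tt0\tworker\tFalse\tAX\n")
        with pytest.raises(ValueError, match="AX"):
            read_tsv(path)

    def test_triallelic_vcf_record_skipped(self, tmp_path, caplog):
        path = tmp_path / "tri.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t1\tok\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "1\t2\tbad\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t1/2\n")
        with caplog.at_level("WARNING"):
            G = read_vcf(path)
        assert G.n_loci == 1 and list(G.loci) == ["ok"]
        assert "1 multi-allelic" in caplog.text

    def test_half_call_treated_as_missing(self, tmp_path):
        path = tmp_path / "half.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t1\tl0\tA\tC\t.\tPASS\t.\tGT\t./1\n")
        assert read_vcf(path).calls[0, 0] == MISSING


class TestObservedHeterozygosity:
    def test_hand_count(self):
        G = make_matrix([[1], [1], [0], [MISSING]])
        assert observed_heterozygosity(G)[0] == pytest.approx(2 / 3)

    def test_extremes(self):
        assert observed_heterozygosity(make_matrix([[0], [2]]))[0] == 0.0
        assert observed_heterozygosity(make_matrix([[1], [1]]))[0] == 1.0

    def test_all_missing_is_nan_not_zero(self):
        G = make_matrix([[MISSING, 0], [MISSING, 1]])
        h = observed_heterozygosity(G)
        assert np.isnan(h[0]) and h[1] == 0.5


class TestFilterIndividuals:
    def test_fully_observed_unchanged(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=5, seed=23)
        G, _ = simulate_colonies(design, panel300)
        assert filter_individuals(G, FilterSettings()).equals(G)

    def test_low_coverage_individual_removed(self):
        calls = np.zeros((5, 10), dtype=np.int8)
        calls[4, :9] = MISSING  # 10% coverage
        G = make_matrix(calls)
        out = filter_individuals(G, FilterSettings(min_coverage=0.2))
        assert list(out.ids) == ["i0", "i1", "i2", "i3"]

    def test_zero_threshold_vacuous(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[2, :9] = MISSING
        G = make_matrix(calls)
        assert filter_individuals(G, FilterSettings(min_coverage=0.0)).equals(G)

    def test_all_removed_is_error(self):
        # diagonal presence: every locus passes a 10% screen but every
        # individual has only 10% coverage over the screened loci
        calls = np.full((10, 10), MISSING, dtype=np.int8)
        np.fill_diagonal(calls, 0)
        G = make_matrix(calls)
        with pytest.raises(ValueError, match="all individuals"):
            filter_individuals(G, FilterSettings(min_coverage=0.2,
                                                 r_prelim=0.1))

    def test_coverage_measured_over_screened_loci(self):
        # locus 1 fails the prelim presence screen and must not count
        calls = np.array([
            [0, MISSING, 0, 0],
            [0, MISSING, 0, 0],
            [0, MISSING, MISSING, MISSING],  # 1/3 over screened loci
        ], dtype=np.int8)
        G = make_matrix(calls)
        out = filter_individuals(
            G, FilterSettings(min_coverage=0.35, r_prelim=0.5))
        assert out.n_individuals == 2


class TestFilterLoci:
    def _fixture(self):
        # 6 loci over 20 individuals: l0 fails the heterozygosity rule
        # (12/20 = 0.6 > 0.5), l1 is fixed (MAF 0 < 0.02); l2-l5 pass all
        # three rules (fully present, H_obs <= 0.5, MAF >= 0.02)
        calls = np.array([
            # l0   l1  l2  l3  l4  l5
            [1,    0,  0,  1,  0,  2],
            [1,    0,  1,  0,  1,  2],
            [1,    0,  1,  0,  0,  2],
            [1,    0,  0,  1,  1,  0],
            [2,    0,  0,  0,  0,  0],
            [1,    0,  1,  1,  0,  0],
            [1,    0,  0,  0,  1,  0],
            [1,    0,  0,  0,  0,  0],
            [2,    0,  1,  1,  0,  2],
            [0,    0,  0,  0,  1,  2],
            [1,    0,  0,  1,  0,  0],
            [0,    0,  1,  0,  0,  0],
            [1,    0,  0,  0,  1,  2],
            [0,    0,  0,  1,  0,  0],
            [1,    0,  1,  0,  0,  2],
            [0,    0,  0,  0,  1,  0],
            [1,    0,  0,  1,  0,  0],
            [0,    0,  1,  0,  0,  2],
            [1,    0,  0,  0,  1,  0],
            [0,    0,  0,  1,  0,  0],
        ], dtype=np.int8)
        return make_matrix(calls)

    def test_het_rule(self):
        # l0: H_obs = 0.6 > 0.5 -> removed; l1: H_obs = 0.4 kept
        G = make_matrix(np.array([[1, 0], [1, 1], [1, 0], [0, 1], [0, 0]],
                                 dtype=np.int8))
        out = filter_loci(G, FilterSettings(min_maf=0.0))
        assert list(out.loci) == ["l1"]

    def test_maf_rule(self):
        # l0: one alt allele in 40 -> MAF 0.025 passes at 0.02; l1: fixed
        calls = np.zeros((20, 3), dtype=np.int8)
        calls[0, 0] = 1
        calls[0, 2] = 1
        calls[1, 2] = 1
        out = filter_loci(make_matrix(calls), FilterSettings(max_het=1.0))
        assert "l1" not in list(out.loci)  # MAF 0 removed
        assert "l0" in list(out.loci)  # MAF 0.025 kept

    def test_known_violations_fixture(self):
        G = self._fixture()
        out = filter_loci(G, FilterSettings())
        h = observed_heterozygosity(G)
        assert h[0] > 0.5  # the constructed het violation
        assert list(out.loci) == ["l2", "l3", "l4", "l5"]

    def test_idempotent(self):
        G = self._fixture()
        once = filter_loci(G, FilterSettings())
        twice = filter_loci(once, FilterSettings())
        assert twice.equals(once)

    def test_presence_rule_per_species(self):
        calls = np.array([[0, 0], [0, MISSING], [0, MISSING], [0, 0]],
                         dtype=np.int8)
        G = GenotypeMatrix(
            calls=calls,
            ids=np.array(["a", "b", "c", "d"], dtype=object),
            species=np.array(["x", "x", "y", "y"], dtype=object),
            tree=np.array(["t"] * 4, dtype=object),
            caste=np.array(["worker"] * 4, dtype=object),
            loci=np.array(["l0", "l1"], dtype=object),
        )
        settings = FilterSettings(presence_r={"y": 0.75}, default_r=0.5,
                                  min_maf=0.0, max_het=1.0)
        out = filter_loci(G, settings)
        # l1 present in 0.5 of both species: passes x (r=.5), fails y (r=.75)
        assert list(out.loci) == ["l0"]

    def test_zero_survivors_is_error(self):
        G = make_matrix(np.zeros((4, 2), dtype=np.int8))  # all fixed loci
        with pytest.raises(ValueError, match="no loci"):
            filter_loci(G, FilterSettings())

    def test_counts_reconcile(self, panel300):
        design = ColonyDesign(n_trees=3, workers_per_tree=5,
                              queens_per_tree=2, seed=24)
        G, _ = simulate_colonies(design, panel300, noisy=True)
        out = apply_filters(G, FilterSettings())
        assert out.n_loci <= G.n_loci
        assert set(out.loci) <= set(G.loci)
        # order preserved
        kept = [l for l in G.loci if l in set(out.loci)]
        assert list(out.loci) == kept
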