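import math

import numpy as np
import pytest

from antcolonykin.matrix import MISSING, AlleleFrequencies
from antcolonykin.sibship import (CandidateQueen, ErrorModel, config_loglik,
                                  count_nested_partitions, enumerate_configs,
                                  infer_maternal_genotypes, queen_prior,
                                  reconstruct)
from antcolonykin.syndata import (ColonyDesign, apply_observation_noise,
                                  draw_allele_frequencies, simulate_colonies)
from tests.conftest import make_matrix


def half_freqs(n):
    return AlleleFrequencies(
        p=np.full(n, 0.5),
        loci=np.array([f"l{j}" for j in range(n)], dtype=object))


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 1), (2, 3), (3, 12)])
    def test_hand_enumerated_counts(self, n, count):
        configs = list(enumerate_configs(n))
        assert len(configs) == count
        assert len(set(configs)) == count  # each exactly once

    def test_matches_bell_recursion(self):
        for n in range(1, 7):
            assert count_nested_partitions(n) == len(
                list(enumerate_configs(n, cap=8)))

    def test_cap_refusal(self):
        with pytest.raises(ValueError, match="anneal"):
            list(enumerate_configs(9, cap=8))


class TestErrorModel:
    def test_rows_are_distributions(self):
        E = ErrorModel(0.01, 0.003).observation_matrix()
        assert np.allclose(E.sum(axis=1), 1.0)

    def test_noiseless_is_identity(self):
        assert np.allclose(ErrorModel(0, 0).observation_matrix(), np.eye(3))

    def test_dropout_moves_hets_to_homs(self):
        E = ErrorModel(0.2, 0.0).observation_matrix()
        assert E[1, 0] == pytest.approx(0.1)
        assert E[1, 1] == pytest.approx(0.8)
        assert E[1, 2] == pytest.approx(0.1)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ErrorModel(dropout=1.0)


class TestConfigLoglik:
    def test_single_worker_marginalizes_to_hwe(self):
        """One hom-ref worker, one locus, p = .5: summing the parental
        states must reproduce the HWE genotype probability 0.25."""
        G = make_matrix([[0]])
        ll = config_loglik(G, [[["i0"]]], half_freqs(1), ErrorModel(0, 0))
        assert math.exp(ll) == pytest.approx(0.25)

    def test_brute_force_parental_sum(self):
        """Direct 3x2 enumeration of (mother genotype, father allele)
        states equals the engine's likelihood for one worker."""
        p = 0.3
        freqs = AlleleFrequencies(p=np.array([p]),
                                  loci=np.array(["l0"], dtype=object))
        for obs in (0, 1, 2):
            G = make_matrix([[obs]])
            ll = config_loglik(G, [[["i0"]]], freqs, ErrorModel(0, 0))
            total = 0.0
            hwe = {0: p * p, 1: 2 * p * (1 - p), 2: (1 - p) * (1 - p)}
            for gm, pgm in hwe.items():
                m_alt = {0: [0.0], 1: [0.0, 1.0], 2: [1.0]}[gm]
                for af, paf in ((0, p), (1, 1 - p)):
                    for ma in m_alt:
                        true = int(ma + af)
                        total += (pgm / len(m_alt)) * paf * (true == obs)
            assert math.exp(ll) == pytest.approx(total)

    def test_incompatible_workers_prefer_split(self):
        """Two workers sharing no alleles: one shared paternal family is
        strictly worse than two separate maternal families."""
        n = 40
        G = make_matrix([[0] * n, [2] * n])
        freqs = half_freqs(n)
        err = ErrorModel(0.0001, 0.0025)
        joint = config_loglik(G, [[["i0", "i1"]]], freqs, err)
        split = config_loglik(G, [[["i0"]], [["i1"]]], freqs, err)
        assert joint < split

    def test_impossible_data_is_neg_inf(self):
        # hom-ref and hom-alt full sisters are impossible without error
        G = make_matrix([[0], [2]])
        ll = config_loglik(G, [[["i0", "i1"]]], half_freqs(1),
                           ErrorModel(0, 0))
        assert ll == -np.inf

    def test_non_cover_partition_rejected(self):
        G = make_matrix([[0], [0]])
        with pytest.raises(ValueError, match="cover"):
            config_loglik(G, [[["i0"]]], half_freqs(1), ErrorModel())
        with pytest.raises(ValueError, match="cover"):
            config_loglik(G, [[["i0", "i0"]], [["i1"]]], half_freqs(1),
                          ErrorModel())

    def test_missing_contributes_one(self):
        G0 = make_matrix([[0]])
        Gm = make_matrix([[0, MISSING]])
        ll0 = config_loglik(G0, [[["i0"]]], half_freqs(1), ErrorModel())
        llm = config_loglik(Gm, [[["i0"]]], half_freqs(2), ErrorModel())
        assert llm == pytest.approx(ll0)

    def test_monotone_evidence_against_wrong_config(self, panel300):
        """In noiseless data, each added informative locus can only widen
        the log-likelihood gap between truth and a wrong configuration."""
        design = ColonyDesign(n_trees=1, workers_per_tree=4,
                              queens_per_tree=1, males_per_queen=1, seed=40)
        G, truth = simulate_colonies(design, panel300)
        ids = list(G.ids)
        true_cfg = [[ids]]  # one mother, one father
        wrong_cfg = [[[ids[0], ids[1]]], [[ids[2], ids[3]]]]
        err = ErrorModel(0, 0)
        prev_margin = np.inf
        for n_loci in (50, 150, 300):
            sub = G.take_loci(np.arange(n_loci))
            fr = AlleleFrequencies(p=panel300.p[:n_loci],
                                   loci=panel300.loci[:n_loci])
            margin = (config_loglik(sub, wrong_cfg, fr, err)
                      - config_loglik(sub, true_cfg, fr, err))
            assert margin <= prev_margin + 1e-9
            prev_margin = margin


class TestReconstruct:
    def test_monogyne_recovered(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=6,
                              queens_per_tree=1, males_per_queen=1, seed=41)
        G, _ = simulate_colonies(design, panel300)
        cfg = reconstruct(G, panel300, ErrorModel(), search="exhaustive")
        assert cfg.n_mothers == 1 and cfg.n_fathers == 1

    def test_three_queens_recovered(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=6,
                              queens_per_tree=3, males_per_queen=1,
                              skew_concentration=50.0, seed=42)
        G, truth = simulate_colonies(design, panel300)
        true_m = truth.sampled_mother_count("tree0")
        cfg = reconstruct(G, panel300, ErrorModel(), search="anneal", seed=1)
        assert cfg.n_mothers == true_m

    def test_anneal_matches_exhaustive(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=5,
                              queens_per_tree=2, males_per_queen=2, seed=43)
        G, _ = simulate_colonies(design, panel300, noisy=True)
        ex = reconstruct(G, panel300, ErrorModel(), search="exhaustive")
        for seed in range(10):
            an = reconstruct(G, panel300, ErrorModel(), search="anneal",
                             seed=seed)
            assert an.log_likelihood == pytest.approx(ex.log_likelihood)

    def test_mother_count_never_exceeds_workers(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=4,
                              queens_per_tree=3, males_per_queen=3, seed=44)
        G, _ = simulate_colonies(design, panel300, noisy=True)
        cfg = reconstruct(G, panel300, ErrorModel(), search="anneal", seed=2)
        assert cfg.n_mothers <= G.n_individuals

    def test_deterministic_under_seed(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=6,
                              queens_per_tree=2, seed=45)
        G, _ = simulate_colonies(design, panel300, noisy=True)
        a = reconstruct(G, panel300, ErrorModel(), search="anneal", seed=7)
        b = reconstruct(G, panel300, ErrorModel(), search="anneal", seed=7)
        assert a.families == b.families
        assert a.log_likelihood == b.log_likelihood


class TestCandidateQueen:
    def test_matching_candidate_assigned_as_mother(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=6,
                              queens_per_tree=1, males_per_queen=2, seed=46)
        G, truth = simulate_colonies(design, panel300)
        qa = truth.queen_alleles[0]
        queen_calls = (2 - qa.sum(axis=1)).astype(np.int8)
        cand = CandidateQueen(genotype=queen_calls, prior=queen_prior(14))
        cfg = reconstruct(G, panel300, ErrorModel(), candidate=cand,
                          search="exhaustive")
        assert cfg.n_mothers == 1
        assert cfg.candidate_assigned == [True]

    def test_unrelated_candidate_not_assigned(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=6,
                              queens_per_tree=1, males_per_queen=2, seed=47)
        G, _ = simulate_colonies(design, panel300)
        rng = np.random.default_rng(48)
        stranger = rng.binomial(2, 1 - panel300.p).astype(np.int8)
        cand = CandidateQueen(genotype=stranger, prior=queen_prior(14))
        cfg = reconstruct(G, panel300, ErrorModel(), candidate=cand,
                          search="exhaustive")
        assert cfg.candidate_assigned == [False]

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            CandidateQueen(genotype=np.zeros(3, dtype=np.int8), prior=0.0)
        assert queen_prior(50) == pytest.approx(0.01)


class TestMaternalGenotypes:
    def test_confident_posteriors_emitted_intact(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=8,
                              queens_per_tree=1, males_per_queen=2, seed=49)
        G, truth = simulate_colonies(design, panel300)
        cfg = reconstruct(G, panel300, ErrorModel(), search="anneal", seed=3)
        mothers = infer_maternal_genotypes(cfg, "tree0", threshold=0.90)
        true_calls = (2 - truth.queen_alleles[0].sum(axis=1)).astype(np.int8)
        called = mothers.calls[0] != MISSING
        assert called.mean() > 0.5  # most loci confidently recovered
        assert np.array_equal(mothers.calls[0][called], true_calls[called])

    def test_low_confidence_alleles_masked(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=2,
                              queens_per_tree=1, males_per_queen=1, seed=50)
        G, _ = simulate_colonies(design, panel300)
        cfg = reconstruct(G, panel300, ErrorModel(), search="exhaustive")
        strict = infer_maternal_genotypes(cfg, "t", threshold=0.9999)
        loose = infer_maternal_genotypes(cfg, "t", threshold=0.0)
        assert (strict.calls == MISSING).sum() > 0
        assert (loose.calls == MISSING).sum() == 0
        # masking only removes calls, never alters retained ones
        kept = strict.calls != MISSING
        assert np.array_equal(strict.calls[kept], loose.calls[kept])

    def test_threshold_validation(self, panel300):
        design = ColonyDesign(n_trees=1, workers_per_tree=2, seed=51)
        G, _ = simulate_colonies(design, panel300)
        cfg = reconstruct(G, panel300, ErrorModel(), search="exhaustive")
        with pytest.raises(ValueError):
            infer_maternal_genotypes(cfg, "t", threshold=1.5)
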