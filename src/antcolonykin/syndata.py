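"""Synthetic colonies and dyads with known pedigree ground truth.

Emulates the post-SNP-calling data of a multi-colony social-insect study:
each tree hosts one colony with ``Q`` egg-laying queens, each queen mated to
``M`` haploid males, and ``n_w`` sampled workers per tree.  Under
haplodiploidy a worker inherits one uniformly chosen maternal allele plus her
father's single haplotype allele at every locus, which is the signal that
makes paternity reconstructable from workers alone.  A diplodiploid mode (two
diploid parents) is provided for estimator-evaluation dyads.

Observation noise follows a two-class genotyping-error model (allelic dropout
on heterozygotes, then a per-allele miscall) plus i.i.d. per-genotype
missingness, matching the error model assumed by the sibship likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, AlleleFrequencies, GenotypeMatrix

RELATIONSHIPS = ("parent-offspring", "full-sib", "half-sib", "unrelated")

#: expected relatedness by relationship class for diploid-by-diploid dyads
TRUE_R_DIPLODIPLOID = {
    "parent-offspring": 0.5,
    "full-sib": 0.5,
    "half-sib": 0.25,
    "unrelated": 0.0,
}
#: expected relatedness for female-female dyads under haplodiploidy
TRUE_R_HAPLODIPLOID = {
    "parent-offspring": 0.5,
    "full-sib": 0.75,
    "half-sib": 0.25,
    "unrelated": 0.0,
}


def _calls_from_alleles(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Unordered genotype code from two allele arrays (1 = reference)."""
    return (2 - (a1.astype(np.int8) + a2.astype(np.int8))).astype(np.int8)


@dataclass
class ColonyDesign:
    """Design of a synthetic multi-tree colony sample.

    Parameters
    ----------
    n_trees : int
        Number of trees (one colony per tree).
    workers_per_tree : int
        Workers sampled per tree (field scale: ~6).
    queens_per_tree : int
        Egg-laying queens per colony.
    males_per_queen : int
        Haploid mates per queen.
    skew_concentration : float
        Concentration of the symmetric Dirichlet over queen offspring
        shares.  Small values give a dominant queen; 0.35 yields a mean
        dominant-queen share near 0.6 at Q = 3 (the range observed for
        polygynous acacia-ant colonies).  Ignored if ``dominant_share``
        is set.
    dominant_share : float or None
        Explicit offspring share of one dominant queen; the remainder is
        split evenly among the other queens.
    p_sister_queens : float
        Probability that a queen belongs to her tree's natal sister cohort
        (daughters of one auxiliary mother-father pair).  Two cohort members
        are full sisters, so a random queen pair is sisters with probability
        about this value squared.
    inheritance : {'haplodiploid', 'diplodiploid'}
    dropout_rate, miscall_rate, p_missing : float
        Observation-noise parameters applied by ``simulate_colonies`` when
        ``noisy`` is true (defaults mirror the sibship error model and a
        field-realistic missingness).
    seed : int
    species_name : str
        Species label stamped on every generated individual.
    """

    n_trees: int = 14
    workers_per_tree: int = 6
    queens_per_tree: int = 1
    males_per_queen: int = 1
    skew_concentration: float = 0.35
    dominant_share: float | None = None
    p_sister_queens: float = 0.0
    inheritance: str = "haplodiploid"
    dropout_rate: float = 0.0001
    miscall_rate: float = 0.0025
    p_missing: float = 0.3
    seed: int = 0
    species_name: str = "sim"

    def __post_init__(self) -> None:
        if min(self.n_trees, self.workers_per_tree, self.queens_per_tree,
               self.males_per_queen) < 1:
            raise ValueError("counts must all be >= 1")
        if self.inheritance not in ("haplodiploid", "diplodiploid"):
            raise ValueError(f"unknown inheritance mode: {self.inheritance!r}")
        for name in ("p_sister_queens", "dropout_rate", "miscall_rate",
                     "p_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.skew_concentration <= 0:
            raise ValueError("skew_concentration must be positive")
        if self.dominant_share is not None and not (
                0.0 < self.dominant_share <= 1.0):
            raise ValueError("dominant_share must be in (0, 1]")


@dataclass
class PedigreeTruth:
    """Simulator ground truth for parameter-recovery tests.

    Parental genotypes are stored as allele arrays with 1 = reference allele.
    ``mat_chrom``/``pat_chrom`` record which parental chromosome each worker
    inherited per locus, so realized identity-by-descent sharing between any
    two workers can be computed exactly.
    """

    queen_ids: np.ndarray
    queen_tree: np.ndarray
    queen_alleles: np.ndarray  # (n_queens, n_loci, 2)
    father_ids: np.ndarray
    father_queen: np.ndarray  # mating set: father -> queen id
    father_alleles: np.ndarray  # (n_fathers, n_loci) or (..., 2) if diploid
    worker_ids: np.ndarray
    worker_mother: np.ndarray
    worker_father: np.ndarray
    mat_chrom: np.ndarray  # (n_workers, n_loci) in {0,1}
    pat_chrom: np.ndarray  # all zero under haplodiploidy
    queen_sibling_pairs: set = field(default_factory=set)
    inheritance: str = "haplodiploid"

    def _queen_row(self, qid) -> int:
        return int(np.flatnonzero(self.queen_ids == qid)[0])

    def _father_row(self, fid) -> int:
        return int(np.flatnonzero(self.father_ids == fid)[0])

    def worker_alleles(self, w: int) -> tuple[np.ndarray, np.ndarray]:
        """(maternal, paternal) allele arrays of worker row ``w``, pre-noise."""
        q = self._queen_row(self.worker_mother[w])
        f = self._father_row(self.worker_father[w])
        L = self.queen_alleles.shape[1]
        mat = self.queen_alleles[q, np.arange(L), self.mat_chrom[w]]
        if self.inheritance == "haplodiploid":
            pat = self.father_alleles[f]
        else:
            pat = self.father_alleles[f, np.arange(L), self.pat_chrom[w]]
        return mat, pat

    def true_calls(self) -> np.ndarray:
        """Noiseless genotype codes for every worker."""
        out = np.empty((len(self.worker_ids), self.queen_alleles.shape[1]),
                       dtype=np.int8)
        for w in range(len(self.worker_ids)):
            mat, pat = self.worker_alleles(w)
            out[w] = _calls_from_alleles(mat, pat)
        return out

    def realized_ibd(self, w1: int, w2: int) -> float:
        """Fraction of allele copies shared identical-by-descent between two
        workers, averaged over loci (the realized-relatedness oracle)."""
        L = self.mat_chrom.shape[1]
        shared = np.zeros(L)
        if self.worker_mother[w1] == self.worker_mother[w2]:
            shared += (self.mat_chrom[w1] == self.mat_chrom[w2])
        if self.worker_father[w1] == self.worker_father[w2]:
            if self.inheritance == "haplodiploid":
                shared += 1.0  # single paternal haplotype, always shared
            else:
                shared += (self.pat_chrom[w1] == self.pat_chrom[w2])
        return float(np.mean(shared / 2.0))

    def sampled_mother_count(self, tree) -> int:
        """Distinct mothers among the workers sampled from one tree."""
        trees = self.queen_tree_of_workers()
        return len(set(self.worker_mother[trees == tree]))

    def sampled_father_count(self, tree) -> int:
        trees = self.queen_tree_of_workers()
        return len(set(self.worker_father[trees == tree]))

    def queen_tree_of_workers(self) -> np.ndarray:
        tree_of_queen = dict(zip(self.queen_ids, self.queen_tree))
        return np.array([tree_of_queen[m] for m in self.worker_mother],
                        dtype=object)


def draw_allele_frequencies(n_loci: int, maf_low: float = 0.1,
                            maf_high: float = 0.5,
                            seed: int = 0) -> AlleleFrequencies:
    """Draw a SNP panel with minor-allele frequencies uniform on
    ``[maf_low, maf_high]`` and randomized reference/alternate orientation."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    p = np.where(flip, 1.0 - maf, maf)
    # guard the open-interval invariant at maf_high = 0.5 exactly
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    loci = np.array([f"locus{i}" for i in range(n_loci)], dtype=object)
    return AlleleFrequencies(p=p, loci=loci)


def _draw_diploid(rng: np.random.Generator, p: np.ndarray,
                  n: int) -> np.ndarray:
    """n diploid genotypes under Hardy-Weinberg: (n, L, 2) allele array."""
    return (rng.random((n, p.size, 2)) < p[None, :, None]).astype(np.int8)


def _draw_haploid(rng: np.random.Generator, p: np.ndarray,
                  n: int) -> np.ndarray:
    return (rng.random((n, p.size)) < p).astype(np.int8)


def _queen_shares(rng: np.random.Generator, design: ColonyDesign) -> np.ndarray:
    Q = design.queens_per_tree
    if Q == 1:
        return np.ones(1)
    if design.dominant_share is not None:
        d = design.dominant_share
        shares = np.full(Q, (1.0 - d) / (Q - 1))
        shares[0] = d
        return rng.permutation(shares)
    return rng.dirichlet(np.full(Q, design.skew_concentration))


def simulate_colonies(
    design: ColonyDesign, freqs: AlleleFrequencies, *, noisy: bool = False
) -> tuple[GenotypeMatrix, PedigreeTruth]:
    """Simulate workers for every tree of a design, with full pedigree truth.

    Queens in a tree's natal sister cohort are generated as daughters of one
    auxiliary mother-father pair (full sisters); remaining queens are
    independent Hardy-Weinberg draws.  Workers are allocated to queens by the
    skew distribution and to each queen's mates uniformly.

    With ``noisy=True`` the design's dropout/miscall/missingness rates are
    applied via :func:`apply_observation_noise`; the returned truth is always
    pre-noise.
    """
    rng = np.random.default_rng(design.seed)
    p = freqs.p
    L = p.size
    haplo = design.inheritance == "haplodiploid"

    queen_ids, queen_tree, queen_alleles = [], [], []
    father_ids, father_queen, father_alleles = [], [], []
    worker_ids, worker_mother, worker_father = [], [], []
    mat_chrom, pat_chrom, worker_tree, calls = [], [], [], []
    sib_pairs: set = set()

    for t in range(design.n_trees):
        tree = f"tree{t}"
        # auxiliary natal pair for the sister-queen cohort
        aux_mother = _draw_diploid(rng, p, 1)[0]
        aux_father = (_draw_haploid(rng, p, 1)[0] if haplo
                      else _draw_diploid(rng, p, 1)[0])
        cohort = []
        for q in range(design.queens_per_tree):
            qid = f"{tree}_Q{q}"
            if rng.random() < design.p_sister_queens:
                m_allele = aux_mother[np.arange(L),
                                      rng.integers(0, 2, size=L)]
                if haplo:
                    f_allele = aux_father
                else:
                    f_allele = aux_father[np.arange(L),
                                          rng.integers(0, 2, size=L)]
                g = np.stack([m_allele, f_allele], axis=-1)
                cohort.append(qid)
            else:
                g = _draw_diploid(rng, p, 1)[0]
            queen_ids.append(qid)
            queen_tree.append(tree)
            queen_alleles.append(g)
            for m in range(design.males_per_queen):
                father_ids.append(f"{qid}_M{m}")
                father_queen.append(qid)
                father_alleles.append(
                    _draw_haploid(rng, p, 1)[0] if haplo
                    else _draw_diploid(rng, p, 1)[0])
        for i, a in enumerate(cohort):
            for b in cohort[i + 1:]:
                sib_pairs.add(frozenset((a, b)))

        shares = _queen_shares(rng, design)
        q_of_worker = rng.choice(design.queens_per_tree,
                                 size=design.workers_per_tree, p=shares)
        for w, q in enumerate(q_of_worker):
            qid = f"{tree}_Q{q}"
            m = rng.integers(design.males_per_queen)
            fid = f"{qid}_M{m}"
            wid = f"{tree}_W{w}"
            qrow = len(queen_ids) - design.queens_per_tree + q
            frow = father_ids.index(fid)
            mc = rng.integers(0, 2, size=L)
            mat = queen_alleles[qrow][np.arange(L), mc]
            if haplo:
                pc = np.zeros(L, dtype=np.int64)
                pat = father_alleles[frow]
            else:
                pc = rng.integers(0, 2, size=L)
                pat = father_alleles[frow][np.arange(L), pc]
            worker_ids.append(wid)
            worker_mother.append(qid)
            worker_father.append(fid)
            worker_tree.append(tree)
            mat_chrom.append(mc)
            pat_chrom.append(pc)
            calls.append(_calls_from_alleles(mat, pat))

    n = len(worker_ids)
    G = GenotypeMatrix(
        calls=np.array(calls, dtype=np.int8),
        ids=np.array(worker_ids, dtype=object),
        species=np.full(n, design.species_name, dtype=object),
        tree=np.array(worker_tree, dtype=object),
        caste=np.full(n, "worker", dtype=object),
        loci=freqs.loci,
    )
    truth = PedigreeTruth(
        queen_ids=np.array(queen_ids, dtype=object),
        queen_tree=np.array(queen_tree, dtype=object),
        queen_alleles=np.array(queen_alleles, dtype=np.int8),
        father_ids=np.array(father_ids, dtype=object),
        father_queen=np.array(father_queen, dtype=object),
        father_alleles=np.array(father_alleles, dtype=np.int8),
        worker_ids=np.array(worker_ids, dtype=object),
        worker_mother=np.array(worker_mother, dtype=object),
        worker_father=np.array(worker_father, dtype=object),
        mat_chrom=np.array(mat_chrom),
        pat_chrom=np.array(pat_chrom),
        queen_sibling_pairs=sib_pairs,
        inheritance=design.inheritance,
    )
    if noisy:
        G = apply_observation_noise(
            G, design.dropout_rate, design.miscall_rate, design.p_missing,
            seed=int(rng.integers(2**31)))
    return G, truth


def apply_observation_noise(G: GenotypeMatrix, dropout_rate: float,
                            miscall_rate: float, p_missing: float,
                            seed: int = 0) -> GenotypeMatrix:
    """Apply the two-class genotyping-error model plus missingness.

    Independently per genotype: with ``p_missing`` the call becomes missing;
    otherwise a heterozygote loses one uniformly chosen allele with
    probability ``dropout_rate`` (becoming a false homozygote), and then each
    allele of the (possibly dropout-modified) call is flipped to the
    alternate allele with probability ``miscall_rate``.  Dimensions and
    labels are unchanged.
    """
    for name, v in (("dropout_rate", dropout_rate),
                    ("miscall_rate", miscall_rate),
                    ("p_missing", p_missing)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = G.calls.copy()
    observed = calls != MISSING

    # stage 1: allelic dropout on heterozygotes
    het = observed & (calls == 1)
    drop = het & (rng.random(calls.shape) < dropout_rate)
    calls[drop] = np.where(rng.random(calls.shape)[drop] < 0.5, 0, 2)

    # stage 2: per-allele miscall; genotype is (# alt alleles) so a flip of a
    # ref allele adds one, a flip of an alt allele subtracts one
    if miscall_rate > 0:
        n_ref = 2 - calls  # ref-allele count per call (valid where observed)
        flips_ref = rng.binomial(np.where(observed, n_ref, 0), miscall_rate)
        flips_alt = rng.binomial(np.where(observed, calls, 0) *
                                 observed.astype(int), miscall_rate)
        calls = np.where(observed, calls + flips_ref - flips_alt, calls)

    miss = rng.random(calls.shape) < p_missing
    calls[miss] = MISSING
    return GenotypeMatrix(calls=calls.astype(np.int8), ids=G.ids,
                          species=G.species, tree=G.tree, caste=G.caste,
                          loci=G.loci, excluded=G.excluded)


def simulate_relationship_pairs(
    relationship: str, n_pairs: int, freqs: AlleleFrequencies,
    mode: str = "diplodiploid", seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate dyads of one relationship class via explicit tiny pedigrees.

    Returns a matrix of ``2 * n_pairs`` individuals (pair members share a
    tree label ``pair<k>``) and the class's expected relatedness per pair
    (0.5 / 0.5 / 0.25 / 0 for diplodiploid parent-offspring, full-sib,
    half-sib, unrelated; the haplodiploid full-sib value is 0.75).
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(
            f"unknown relationship {relationship!r}; one of {RELATIONSHIPS}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if mode not in ("diplodiploid", "haplodiploid"):
        raise ValueError(f"unknown inheritance mode: {mode!r}")
    rng = np.random.default_rng(seed)
    p = freqs.p
    L = p.size
    haplo = mode == "haplodiploid"

    def offspring(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
        mat = mother[np.arange(L), rng.integers(0, 2, size=L)]
        if haplo:
            pat = father
        else:
            pat = father[np.arange(L), rng.integers(0, 2, size=L)]
        return _calls_from_alleles(mat, pat)

    def draw_father() -> np.ndarray:
        return (_draw_haploid(rng, p, 1)[0] if haplo
                else _draw_diploid(rng, p, 1)[0])

    calls, ids, tree = [], [], []
    for k in range(n_pairs):
        mother = _draw_diploid(rng, p, 1)[0]
        father = draw_father()
        if relationship == "parent-offspring":
            a = _calls_from_alleles(mother[:, 0], mother[:, 1])
            b = offspring(mother, father)
        elif relationship == "full-sib":
            a = offspring(mother, father)
            b = offspring(mother, father)
        elif relationship == "half-sib":
            a = offspring(mother, father)
            b = offspring(mother, draw_father())
        else:  # unrelated
            other = _draw_diploid(rng, p, 1)[0]
            a = _calls_from_alleles(mother[:, 0], mother[:, 1])
            b = _calls_from_alleles(other[:, 0], other[:, 1])
        calls.extend([a, b])
        ids.extend([f"pair{k}_a", f"pair{k}_b"])
        tree.extend([f"pair{k}", f"pair{k}"])

    n = 2 * n_pairs
    G = GenotypeMatrix(
        calls=np.array(calls, dtype=np.int8),
        ids=np.array(ids, dtype=object),
        species=np.full(n, "sim", dtype=object),
        tree=np.array(tree, dtype=object),
        caste=np.full(n, "worker", dtype=object),
        loci=freqs.loci,
    )
    table = TRUE_R_HAPLODIPLOID if haplo else TRUE_R_DIPLODIPLOID
    return G, np.full(n_pairs, table[relationship])
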