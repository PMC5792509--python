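"""Maximum-likelihood sibship and parentage reconstruction.

A tree's sampled workers are partitioned into maternal families (one
unobserved diploid mother each) subdivided into paternal families (one
unobserved father each).  Under haplodiploidy a father is haploid, so all
his daughters receive the identical allele at every locus — the constraint
that gives paternity its signal.  A diplodiploid mode (diploid fathers,
Hardy-Weinberg prior) is used when the "offspring" are themselves diploid
reconstructed queens.

Likelihood model
----------------
Loci are independent, and parental genotypes are integrated out locus by
locus (parents independent across loci given the partition), which keeps
the per-locus model exact and exhaustive enumeration feasible.  Per
maternal family and locus,

    L = sum_{G_m} P(G_m) * prod_f [ sum_{a_f} P(a_f)
            * prod_{w in f} P(obs_w | G_m, a_f) ]

with Hardy-Weinberg priors from the supplied allele frequencies (or a point
mass at a candidate queen's genotype).  The observation kernel is the
two-class genotyping-error model: a true heterozygote drops to either
homozygote with probability eps_d/2 each, then each allele is miscalled
with probability eps_o; missing observations contribute likelihood 1.

A known candidate queen with per-offspring prior pi enters each maternal
family as a two-component mixture, pi * L(mother = candidate) +
(1 - pi) * L(mother ~ HWE); she is reported as assigned where her posterior
weight exceeds one half.

Search is either exhaustive enumeration of all nested partitions (small
families; also the oracle) or simulated annealing over split/merge/move
proposals followed by a greedy single-worker polish.  Total log-likelihood
decomposes over maternal families, so both searches cache per-family terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .matrix import MISSING, AlleleFrequencies, GenotypeMatrix

logger = logging.getLogger(__name__)

# canonical nested partition: tuple of maternal families, each a tuple of
# paternal families, each a sorted tuple of worker row indices; families
# ordered by their smallest member
Nested = tuple[tuple[tuple[int, ...], ...], ...]


@dataclass(frozen=True)
class ErrorModel:
    """Two-class genotyping-error model (dropout + per-allele miscall)."""

    dropout: float = 0.0001
    miscall: float = 0.0025

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0 and 0.0 <= self.miscall < 1.0):
            raise ValueError("error rates must lie in [0, 1)")

    def observation_matrix(self) -> np.ndarray:
        """3x3 matrix E[true, observed] over genotype codes 0/1/2."""
        d, o = self.dropout, self.miscall
        drop = np.array([[1.0, 0.0, 0.0],
                         [d / 2, 1.0 - d, d / 2],
                         [0.0, 0.0, 1.0]])
        flip = np.array([
            [(1 - o) ** 2, 2 * o * (1 - o), o ** 2],
            [o * (1 - o), (1 - o) ** 2 + o ** 2, o * (1 - o)],
            [o ** 2, 2 * o * (1 - o), (1 - o) ** 2],
        ])
        return drop @ flip


@dataclass
class CandidateQueen:
    """A sampled queen offered as possible mother of each family.

    ``prior`` is the prior probability that she is the mother of any one
    offspring; the conventional default is 0.5 divided by the number of
    trees in the data set.
    """

    genotype: np.ndarray  # calls over the same loci as the workers
    prior: float
    id: str = "candidate"

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        if not 0.0 < self.prior < 1.0:
            raise ValueError("candidate prior must lie in (0, 1)")


def queen_prior(n_trees: int) -> float:
    """Default candidate-queen prior: .5 divided by the number of trees."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    return 0.5 / n_trees


@dataclass
class SibshipConfig:
    """A reconstructed nested family structure for one worker set."""

    worker_ids: np.ndarray
    #: nested partition over worker ids (maternal -> paternal -> ids)
    families: list
    log_likelihood: float
    #: per maternal family: (n_loci, 3) posterior over mother genotypes
    mother_posteriors: list
    #: per maternal family: list of (n_loci, J) father-state posteriors
    father_posteriors: list
    candidate_assigned: list
    loci: np.ndarray
    ploidy: str = "haplodiploid"

    @property
    def n_mothers(self) -> int:
        return len(self.families)

    @property
    def n_fathers(self) -> int:
        return sum(len(m) for m in self.families)

    def family_of(self, worker_id) -> tuple[int, int]:
        for i, m in enumerate(self.families):
            for j, f in enumerate(m):
                if worker_id in f:
                    return i, j
        raise KeyError(worker_id)


# ---------------------------------------------------------------------------
# likelihood engine

class _Engine:
    """Cached per-family likelihood terms for one worker slice."""

    def __init__(self, calls: np.ndarray, freqs: AlleleFrequencies,
                 err: ErrorModel, candidate: CandidateQueen | None,
                 ploidy: str = "haplodiploid") -> None:
        if ploidy not in ("haplodiploid", "diplodiploid"):
            raise ValueError(f"unknown ploidy {ploidy!r}")
        self.ploidy = ploidy
        self.calls = np.asarray(calls, dtype=np.int8)
        self.n, self.L = self.calls.shape
        if freqs.n_loci != self.L:
            raise ValueError("frequency panel does not match locus count")
        p = freqs.p
        q = 1.0 - p
        self.candidate = candidate

        E = err.observation_matrix()
        # maternal / paternal transmitted-allele alt probabilities per state
        m_alt = np.array([0.0, 0.5, 1.0])
        if ploidy == "haplodiploid":
            f_alt = np.array([0.0, 1.0])  # haploid father allele
            self.log_father_prior = np.log(np.stack([p, q]))  # (2, L)
        else:
            f_alt = np.array([0.0, 0.5, 1.0])  # diploid father genotype
            self.log_father_prior = np.log(
                np.stack([p ** 2, 2 * p * q, q ** 2]))  # (3, L)
        J = f_alt.size
        T = np.empty((3, J, 3))
        for i, mi in enumerate(m_alt):
            for j, fj in enumerate(f_alt):
                T[i, j] = [(1 - mi) * (1 - fj),
                           mi * (1 - fj) + (1 - mi) * fj,
                           mi * fj]
        W = T @ E  # (3, J, 3): P(obs | G_m, father state)
        with np.errstate(divide="ignore"):
            logW = np.log(W)
        # extend with an always-1 column for missing observations
        self.logW = np.concatenate(
            [logW, np.zeros((3, J, 1))], axis=2)  # (3, J, 4)
        self.obs = np.where(self.calls == MISSING, 3, self.calls)  # (n, L)

        with np.errstate(divide="ignore"):
            self.log_hwe_mother = np.log(
                np.stack([p ** 2, 2 * p * q, q ** 2]))  # (3, L)
        if candidate is not None:
            cg = candidate.genotype
            if cg.shape != (self.L,):
                raise ValueError("candidate genotype length mismatch")
            lp = np.full((3, self.L), -np.inf)
            seen = cg != MISSING
            lp[:, ~seen] = self.log_hwe_mother[:, ~seen]
            lp[cg[seen], np.flatnonzero(seen)] = 0.0
            self.log_candidate_mother = lp
        self._cache: dict = {}

    # -- per-family terms ---------------------------------------------------

    def _paternal_logterm(self, members: tuple[int, ...]) -> np.ndarray:
        """(3, L) log of the father-marginalized term for one paternal
        family, as a function of the mother genotype."""
        A = self.logW[:, :, self.obs[list(members)]].sum(axis=2)  # (3,J,L)
        return logsumexp(A + self.log_father_prior[None, :, :], axis=1)

    def _family_branch(self, fam: tuple[tuple[int, ...], ...]
                       ) -> tuple[float, float]:
        """(HWE-mother, candidate-mother) log-likelihoods of one maternal
        family; the candidate value is -inf when no candidate is supplied."""
        S = sum(self._paternal_logterm(pf) for pf in fam)  # (3, L)
        ll_hwe = float(logsumexp(self.log_hwe_mother + S, axis=0).sum())
        if self.candidate is None:
            return ll_hwe, -np.inf
        ll_cand = float(
            logsumexp(self.log_candidate_mother + S, axis=0).sum())
        return ll_hwe, ll_cand

    def family_loglik(self, fam: tuple[tuple[int, ...], ...]) -> float:
        """Log-likelihood of one maternal family (candidate mixture)."""
        if fam not in self._cache:
            ll_hwe, ll_cand = self._family_branch(fam)
            if self.candidate is None:
                ll = ll_hwe
            else:
                pi = self.candidate.prior
                ll = np.logaddexp(math.log(pi) + ll_cand,
                                  math.log1p(-pi) + ll_hwe)
            self._cache[fam] = float(ll)
        return self._cache[fam]

    def config_loglik(self, nested: Nested) -> float:
        return sum(self.family_loglik(fam) for fam in nested)

    # -- posteriors ---------------------------------------------------------

    def posteriors(self, fam: tuple[tuple[int, ...], ...]
                   ) -> tuple[np.ndarray, list, bool]:
        """Mother-genotype and father-state posteriors for one family.

        Returns ``(mother_post (L, 3), [father_post (L, J) per paternal
        family], candidate_assigned)``.  The mother prior is the candidate
        point mass when her mixture posterior exceeds 0.5, else HWE.
        """
        assigned = False
        log_prior = self.log_hwe_mother
        if self.candidate is not None:
            ll_hwe, ll_cand = self._family_branch(fam)
            pi = self.candidate.prior
            a = math.log(pi) + ll_cand
            b = math.log1p(-pi) + ll_hwe
            assigned = a > b
            if assigned:
                log_prior = self.log_candidate_mother
        terms = [self._paternal_logterm(pf) for pf in fam]  # (3, L) each
        C = log_prior + sum(terms)  # (3, L)
        logZ = logsumexp(C, axis=0)
        mother_post = np.exp(C - logZ).T  # (L, 3)
        father_posts = []
        for pf, term in zip(fam, terms):
            A = (self.logW[:, :, self.obs[list(pf)]].sum(axis=2)
                 + self.log_father_prior[None, :, :])  # (3, J, L)
            # P(a_f | G_m) weighted by the mother posterior
            with np.errstate(invalid="ignore"):
                cond = np.exp(A - logsumexp(A, axis=1, keepdims=True))
            cond = np.nan_to_num(cond, nan=1.0 / cond.shape[1])
            post = np.einsum("lg,gjl->lj", mother_post, cond)
            father_posts.append(post)
        return mother_post, father_posts, assigned


# ---------------------------------------------------------------------------
# nested-partition utilities

def canonical(nested) -> Nested:
    """Canonical ordering of a nested partition for hashing/comparison."""
    mats = []
    for fam in nested:
        pfs = sorted(tuple(sorted(pf)) for pf in fam)
        mats.append(tuple(pfs))
    return tuple(sorted(mats, key=lambda m: m[0]))


def _set_partitions(items: list):
    """All set partitions of ``items`` (each exactly once)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def enumerate_configs(n_workers: int, cap: int = 8):
    """Yield every nested (maternal over paternal) partition of ``n_workers``
    workers exactly once.  Refuses above ``cap``; use the annealer instead."""
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if n_workers > cap:
        raise ValueError(
            f"{n_workers} workers exceeds the enumeration cap {cap}; "
            "use search='anneal'")

    def sub_partitions(block):
        return [tuple(tuple(sorted(b)) for b in p)
                for p in _set_partitions(list(block))]

    for maternal in _set_partitions(list(range(n_workers))):
        choices = [sub_partitions(block) for block in maternal]

        def rec(k, acc):
            if k == len(choices):
                yield canonical(acc)
                return
            for sub in choices[k]:
                yield from rec(k + 1, acc + [sub])

        yield from rec(0, [])


def count_nested_partitions(n: int) -> int:
    """Number of nested partitions, via the Bell-number recursion: the sum
    over maternal partitions of the product of Bell(block size)."""
    from math import comb

    bell = [1] * (n + 1)
    for m in range(1, n + 1):
        bell[m] = sum(comb(m - 1, k) * bell[k] for k in range(m))
    # f(n) = sum over size of the block containing element 1
    f = [1] * (n + 1)
    for m in range(1, n + 1):
        f[m] = sum(comb(m - 1, s - 1) * bell[s] * f[m - s]
                   for s in range(1, m + 1))
    return f[n]


# ---------------------------------------------------------------------------
# search

def config_loglik(workers: GenotypeMatrix, config,
                  freqs: AlleleFrequencies, err: ErrorModel,
                  candidate: CandidateQueen | None = None,
                  ploidy: str = "haplodiploid") -> float:
    """Log-likelihood of an explicit nested family structure.

    ``config`` is a nested sequence (maternal families of paternal families)
    of worker ids, which must cover the supplied workers exactly once each.
    Impossible data under a zero-error model yield ``-inf`` (flagged by a
    warning rather than an exception).
    """
    idx = {wid: k for k, wid in enumerate(workers.ids)}
    seen = []
    nested = []
    for fam in config:
        pfs = []
        for pf in fam:
            rows = tuple(sorted(idx[w] for w in pf))
            seen.extend(rows)
            pfs.append(rows)
        nested.append(tuple(pfs))
    if sorted(seen) != list(range(workers.n_individuals)):
        raise ValueError("config is not an exact cover of the workers")
    eng = _Engine(workers.calls, freqs, err, candidate, ploidy)
    ll = eng.config_loglik(canonical(nested))
    if not np.isfinite(ll):
        logger.warning("configuration has zero likelihood (impossible data "
                       "under the error model)")
    return ll


def _tie_key(ll: float, nested: Nested) -> tuple:
    """Sort key: maximize log-likelihood, then prefer fewer mothers, then
    fewer fathers."""
    n_mothers = len(nested)
    n_fathers = sum(len(m) for m in nested)
    return (ll, -n_mothers, -n_fathers)


def _greedy_polish(eng: _Engine, nested: Nested) -> Nested:
    """Repeated best single-worker reassignment until no move improves.

    Candidate moves place one worker into any existing paternal family, a
    new paternal family of any maternal family, or a brand-new maternal
    family.  Ties in likelihood resolve toward parsimony.
    """
    current = [list(map(list, fam)) for fam in nested]

    def score(struct):
        c = canonical([tuple(map(tuple, fam)) for fam in struct if fam])
        return eng.config_loglik(c), c

    best_ll, best_c = score(current)
    improved = True
    while improved:
        improved = False
        workers = sorted(w for fam in best_c for pf in fam for w in pf)
        for w in workers:
            base = [[list(pf) for pf in fam] for fam in best_c]
            for fam in base:
                for pf in fam:
                    if w in pf:
                        pf.remove(w)
                fam[:] = [pf for pf in fam if pf]
            base = [fam for fam in base if fam]
            # all placements of w
            options = []
            for i, fam in enumerate(base):
                for j in range(len(fam)):
                    options.append((i, j))
                options.append((i, None))  # new paternal family
            options.append((None, None))  # new maternal family
            for i, j in options:
                trial = [[list(pf) for pf in fam] for fam in base]
                if i is None:
                    trial.append([[w]])
                elif j is None:
                    trial[i].append([w])
                else:
                    trial[i][j].append(w)
                ll, c = score(trial)
                if (ll, *_tie_key(ll, c)[1:]) > (best_ll,
                                                 *_tie_key(best_ll, best_c)[1:]):
                    best_ll, best_c = ll, c
                    improved = True
    return best_c


def _anneal(eng: _Engine, n: int, seed: int, n_iter: int | None = None,
            t0: float = 2.0, t_end: float = 0.02) -> Nested:
    """Simulated annealing over nested partitions, then a greedy polish."""
    rng = np.random.default_rng(seed)
    if n_iter is None:
        n_iter = 250 + 120 * n
    cool = (t_end / t0) ** (1.0 / max(n_iter - 1, 1))

    current: list = [[[w]] for w in range(n)]  # all singletons

    def to_nested(struct) -> Nested:
        return canonical([tuple(map(tuple, fam)) for fam in struct if fam])

    cur_c = to_nested(current)
    cur_ll = eng.config_loglik(cur_c)
    best_c, best_ll = cur_c, cur_ll
    temp = t0
    for _ in range(n_iter):
        prop = [[list(pf) for pf in fam] for fam in current]
        kind = rng.integers(5)
        if kind == 0 and n > 1:  # move worker to random placement
            w = int(rng.integers(n))
            for fam in prop:
                for pf in fam:
                    if w in pf:
                        pf.remove(w)
                fam[:] = [pf for pf in fam if pf]
            prop = [fam for fam in prop if fam]
            i = int(rng.integers(len(prop) + 1))
            if i == len(prop):
                prop.append([[w]])
            else:
                j = int(rng.integers(len(prop[i]) + 1))
                if j == len(prop[i]):
                    prop[i].append([w])
                else:
                    prop[i][j].append(w)
        elif kind == 1 and len(prop) > 1:  # merge two maternal families
            i, j = rng.choice(len(prop), size=2, replace=False)
            prop[int(i)].extend(prop[int(j)])
            del prop[int(j)]
        elif kind == 2:  # split a paternal family out into a new mother
            i = int(rng.integers(len(prop)))
            if len(prop[i]) > 1:
                j = int(rng.integers(len(prop[i])))
                prop.append([prop[i].pop(j)])
        elif kind == 3:  # merge two paternal families within a mother
            i = int(rng.integers(len(prop)))
            if len(prop[i]) > 1:
                a, b = rng.choice(len(prop[i]), size=2, replace=False)
                prop[int(i)][int(a)].extend(prop[int(i)][int(b)])
                del prop[int(i)][int(b)]
        else:  # split a worker out into a new paternal family, same mother
            i = int(rng.integers(len(prop)))
            j = int(rng.integers(len(prop[i])))
            if len(prop[i][j]) > 1:
                k = int(rng.integers(len(prop[i][j])))
                w = prop[i][j].pop(k)
                prop[i].append([w])
        prop_c = to_nested(prop)
        if prop_c == cur_c:
            temp *= cool
            continue
        prop_ll = eng.config_loglik(prop_c)
        delta = prop_ll - cur_ll
        if delta >= 0 or (np.isfinite(delta)
                          and rng.random() < math.exp(delta / temp)):
            current = prop
            cur_c, cur_ll = prop_c, prop_ll
            if (cur_ll, *_tie_key(cur_ll, cur_c)[1:]) > (
                    best_ll, *_tie_key(best_ll, best_c)[1:]):
                best_c, best_ll = cur_c, cur_ll
        temp *= cool
    return _greedy_polish(eng, best_c)


def reconstruct(workers: GenotypeMatrix, freqs: AlleleFrequencies,
                err: ErrorModel | None = None,
                candidate: CandidateQueen | None = None,
                search: str = "anneal", seed: int = 0,
                ploidy: str = "haplodiploid",
                enumeration_cap: int = 8) -> SibshipConfig:
    """Reconstruct the maximum-likelihood nested sibship configuration.

    ``search='exhaustive'`` enumerates every nested partition (small worker
    sets only) and returns the global optimum, ties broken toward fewer
    mothers then fewer fathers.  ``search='anneal'`` runs seeded simulated
    annealing with a greedy polish and returns the best configuration
    visited.
    """
    if workers.n_individuals < 1:
        raise ValueError("need at least one worker")
    err = err or ErrorModel()
    eng = _Engine(workers.calls, freqs, err, candidate, ploidy)
    n = workers.n_individuals
    if search == "exhaustive":
        best = None
        for nested in enumerate_configs(n, cap=enumeration_cap):
            ll = eng.config_loglik(nested)
            key = _tie_key(ll, nested)
            if best is None or key > best[0]:
                best = (key, nested)
        nested, ll = best[1], best[0][0]
    elif search == "anneal":
        nested = _anneal(eng, n, seed)
        ll = eng.config_loglik(nested)
    else:
        raise ValueError(f"unknown search mode {search!r}")

    mother_posts, father_posts, assigned = [], [], []
    families = []
    for fam in nested:
        mp, fps, asg = eng.posteriors(fam)
        mother_posts.append(mp)
        father_posts.append(fps)
        assigned.append(asg)
        families.append([[workers.ids[w] for w in pf] for pf in fam])
    return SibshipConfig(
        worker_ids=workers.ids,
        families=families,
        log_likelihood=float(ll),
        mother_posteriors=mother_posts,
        father_posteriors=father_posts,
        candidate_assigned=assigned,
        loci=workers.loci,
        ploidy=ploidy,
    )


# ---------------------------------------------------------------------------
# maternal genotype recovery

def infer_maternal_genotypes(config: SibshipConfig, tree,
                             threshold: float = 0.90,
                             species: str = "sim") -> GenotypeMatrix:
    """Maximum-posterior mother genotypes, low-confidence alleles masked.

    Per mother and locus the maximum-posterior diploid genotype is emitted;
    each allele slot of that genotype carries its own posterior support —
    carriage probability for the allele's first copy, the homozygote
    posterior for a second copy of the same allele — and any slot below
    ``threshold`` is recorded as missing.  A genotype with a masked allele
    becomes a missing call (half-calls carry no information for downstream
    biallelic analyses).  ``threshold = 0`` disables masking.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    calls = []
    ids = []
    for i, post in enumerate(config.mother_posteriors):
        g = np.argmax(post, axis=1).astype(np.int8)  # (L,)
        carries_ref = post[:, 0] + post[:, 1]
        carries_alt = post[:, 2] + post[:, 1]
        keep = np.select(
            [g == 0, g == 1, g == 2],
            [np.minimum(carries_ref, post[:, 0]) >= threshold,
             np.minimum(carries_ref, carries_alt) >= threshold,
             np.minimum(carries_alt, post[:, 2]) >= threshold])
        g = np.where(keep, g, MISSING).astype(np.int8)
        calls.append(g)
        ids.append(f"{tree}_mother{i}")
    n = len(ids)
    return GenotypeMatrix(
        calls=np.array(calls, dtype=np.int8),
        ids=np.array(ids, dtype=object),
        species=np.full(n, species, dtype=object),
        tree=np.full(n, tree, dtype=object),
        caste=np.full(n, "queen", dtype=object),
        loci=config.loci,
    )
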