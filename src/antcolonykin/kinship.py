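"""Pairwise relatedness estimation and within-/between-tree averaging.

Two moment estimators of the relatedness coefficient r are provided, both
computed per reference direction as a ratio of per-locus sums (loci are
thereby weighted by their information content) and then averaged over the
two directions so the estimate is symmetric in the pair.

With the reference individual carrying alleles a, b and the proband c, d,
and S_xy the indicator that alleles x and y are identical in state:

* Lynch-Ritland:
  numerator_l   = p_a (S_bc + S_bd) + p_b (S_ac + S_ad) - 4 p_a p_b
  denominator_l = (1 + S_ab)(p_a + p_b) - 4 p_a p_b
* Queller-Goodnight:
  numerator_l   = 0.5 (S_ac + S_ad + S_bc + S_bd) - p_a - p_b
  denominator_l = 1 + S_ab - p_a - p_b

where p_x is the population frequency of allele x.  Loci missing in either
individual are skipped; a pair with no usable locus (or an all-zero
denominator sum) yields an undefined estimate (NaN), which aggregation
excludes rather than treating as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, AlleleFrequencies, GenotypeMatrix

ESTIMATORS = ("lynch-ritland", "queller-goodnight")


@dataclass(frozen=True)
class PairEstimate:
    id1: str
    id2: str
    estimator: str
    r: float  # NaN if undefined
    n_loci: int


def sample_allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Reference-allele frequency per locus from observed calls.

    p = (2 * hom-ref + het) / (2 * non-missing), pooled across all
    individuals in the matrix (callers pool within species by subsetting
    first).  All-missing loci are an error; fixed loci (p of 0 or 1) are
    degenerate for the estimators and clamped just inside (0, 1) with the
    expectation that they were filtered upstream.
    """
    observed = G.calls != MISSING
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        bad = list(G.loci[n_obs == 0])
        raise ValueError(f"all-missing loci (filter upstream): {bad[:5]}")
    n_ref = np.where(observed, 2 - G.calls, 0).sum(axis=0)
    p = n_ref / (2 * n_obs)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return AlleleFrequencies(p=p, loci=G.loci)


def _directional_terms(gx: np.ndarray, gy: np.ndarray, p: np.ndarray,
                       estimator: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator/denominator with x as the reference individual.

    ``gx``/``gy`` are alternate-allele counts (0, 1, 2).  Closed forms per
    reference genotype follow from substituting allele identities into the
    estimator formulas (n_R, n_A = proband's reference/alternate counts):

    reference hom-ref:  LR  2 p n_R - 4 p^2           /  4 p q
    reference het:      LR  p n_A + q n_R - 4 p q     /  1 - 4 p q
    reference hom-alt:  LR  2 q n_A - 4 q^2           /  4 p q
    reference hom-ref:  QG  n_R - 2 p                 /  2 - 2 p
    reference het:      QG  0                         /  0
    reference hom-alt:  QG  n_A - 2 q                 /  2 - 2 q
    """
    q = 1.0 - p
    n_ref = 2.0 - gy
    n_alt = gy.astype(float)
    if estimator == "lynch-ritland":
        num = np.select(
            [gx == 0, gx == 1, gx == 2],
            [2 * p * n_ref - 4 * p**2,
             p * n_alt + q * n_ref - 4 * p * q,
             2 * q * n_alt - 4 * q**2])
        den = np.select(
            [gx == 0, gx == 1, gx == 2],
            [4 * p * q, 1 - 4 * p * q, 4 * p * q])
    elif estimator == "queller-goodnight":
        num = np.select(
            [gx == 0, gx == 1, gx == 2],
            [n_ref - 2 * p, np.zeros_like(p), n_alt - 2 * q])
        den = np.select(
            [gx == 0, gx == 1, gx == 2],
            [2 - 2 * p, np.zeros_like(p), 2 - 2 * q])
    else:
        raise ValueError(f"unknown estimator {estimator!r}; "
                         f"one of {ESTIMATORS}")
    return num, den


def pair_relatedness(gx: np.ndarray, gy: np.ndarray,
                     freqs: AlleleFrequencies,
                     estimator: str = "lynch-ritland") -> tuple[float, int]:
    """Relatedness estimate for one pair of genotype rows.

    Returns ``(r, n_loci_used)``; ``r`` is NaN when no locus is usable or
    every direction's denominator sum is zero.
    """
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    use = (gx != MISSING) & (gy != MISSING)
    n_used = int(use.sum())
    if n_used == 0:
        return float("nan"), 0
    gx, gy, p = gx[use], gy[use], freqs.p[use]
    vals = []
    for ref, pro in ((gx, gy), (gy, gx)):
        num, den = _directional_terms(ref, pro, p, estimator)
        s = den.sum()
        if s != 0.0:
            vals.append(num.sum() / s)
    if not vals:
        return float("nan"), n_used
    return float(np.mean(vals)), n_used


def pairwise_relatedness(G: GenotypeMatrix, freqs: AlleleFrequencies,
                         estimator: str = "lynch-ritland",
                         pairs=None) -> pd.DataFrame:
    """Relatedness for all (or given) unordered pairs of individuals.

    Returns a frame with columns id1, id2, tree1, tree2, estimator, r,
    n_loci.  Undefined estimates appear as NaN rows.
    """
    if pairs is None:
        pairs = combinations(range(G.n_individuals), 2)
        pairs = list(pairs)
    rows = []
    for i, j in pairs:
        r, n = pair_relatedness(G.calls[i], G.calls[j], freqs, estimator)
        rows.append((G.ids[i], G.ids[j], G.tree[i], G.tree[j],
                     estimator, r, n))
    return pd.DataFrame(rows, columns=["id1", "id2", "tree1", "tree2",
                                       "estimator", "r", "n_loci"])


@dataclass
class TreeRelatednessSummary:
    """Within- and between-tree relatedness, averaged tree-first.

    The sampling unit is the tree (within) or the unordered tree pair
    (between): raw pairwise values are first averaged within each unit,
    then the species mean and its standard error are taken over units.
    """

    per_tree: pd.DataFrame  # columns: tree, mean_r, n_pairs
    per_tree_pair: pd.DataFrame  # columns: tree1, tree2, mean_r, n_pairs
    within_mean: float
    within_se: float
    between_mean: float
    between_se: float


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return float(np.mean(x)), se


def aggregate_within_between(estimates: pd.DataFrame,
                             G: GenotypeMatrix) -> TreeRelatednessSummary:
    """Tree-first averaging of pairwise estimates for one species.

    Pairs involving an individual flagged ``excluded`` (a queen recovered as
    mother of the sampled workers) are dropped; other queens, e.g. one
    recovered as sister to the workers, are retained.  Undefined (NaN)
    estimates are excluded from the averages.  Trees with fewer than two
    usable individuals simply contribute no within-tree value.
    """
    excluded_ids = set(G.ids[G.excluded])
    est = estimates[~(estimates["id1"].isin(excluded_ids)
                      | estimates["id2"].isin(excluded_ids))]
    est = est.dropna(subset=["r"])

    within = est[est["tree1"] == est["tree2"]]
    per_tree = (within.groupby("tree1")["r"]
                .agg(mean_r="mean", n_pairs="size")
                .reset_index().rename(columns={"tree1": "tree"}))

    between = est[est["tree1"] != est["tree2"]].copy()
    key = [tuple(sorted(t)) for t in zip(between["tree1"], between["tree2"])]
    between["pair_key"] = key
    per_pair = (between.groupby("pair_key")["r"]
                .agg(mean_r="mean", n_pairs="size").reset_index())
    per_pair["tree1"] = [k[0] for k in per_pair["pair_key"]]
    per_pair["tree2"] = [k[1] for k in per_pair["pair_key"]]
    per_pair = per_pair[["tree1", "tree2", "mean_r", "n_pairs"]]

    w_mean, w_se = _mean_se(per_tree["mean_r"].to_numpy())
    b_mean, b_se = _mean_se(per_pair["mean_r"].to_numpy())
    return TreeRelatednessSummary(
        per_tree=per_tree, per_tree_pair=per_pair,
        within_mean=w_mean, within_se=w_se,
        between_mean=b_mean, between_se=b_se)
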