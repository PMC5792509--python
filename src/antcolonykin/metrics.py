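"""Colony-structure indices and inferred-queen kinship classification.

From a reconstructed sibship configuration each tree yields:

* Polygyny Index — number of distinct inferred mothers among the sampled
  workers; Polyandry Index — number of distinct inferred fathers.  Both are
  relative, sample-dependent indices (unsampled families are invisible).
* queen (male) dominance — proportion of sampled workers descending from
  the most prolific mother (father).
* males per queen — number of paternal sub-families per mother, counted
  only for mothers with at least ``min_offspring`` sampled workers
  (default 4) so that small families do not understate polyandry.

Inferred queens from all trees can then be pooled and themselves
reconstructed (as diploid offspring of unknown diploid parents) to classify
each queen pair as full-sibling, half-sibling, or unrelated, tabulated by
same-tree versus different-tree strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import AlleleFrequencies, GenotypeMatrix
from .sibship import CandidateQueen, ErrorModel, SibshipConfig, reconstruct


@dataclass
class ColonyMetrics:
    tree: str
    polygyny_index: int
    polyandry_index: int
    queen_dominance: float
    male_dominance: float
    males_per_queen: list  # one entry per mother passing the offspring rule
    n_workers: int


def polygyny_polyandry(config: SibshipConfig, tree: str = "tree",
                       min_offspring: int = 4) -> ColonyMetrics:
    """Colony-structure indices from one tree's sibship configuration."""
    if config.n_mothers == 0:
        raise ValueError("empty sibship configuration")
    fam_sizes = [sum(len(pf) for pf in fam) for fam in config.families]
    pat_sizes = [len(pf) for fam in config.families for pf in fam]
    n_workers = sum(fam_sizes)
    mpq = [len(fam) for fam, s in zip(config.families, fam_sizes)
           if s >= min_offspring]
    return ColonyMetrics(
        tree=tree,
        polygyny_index=config.n_mothers,
        polyandry_index=config.n_fathers,
        queen_dominance=max(fam_sizes) / n_workers,
        male_dominance=max(pat_sizes) / n_workers,
        males_per_queen=mpq,
        n_workers=n_workers,
    )


def metrics_table(per_tree: list[ColonyMetrics]) -> pd.DataFrame:
    rows = [(m.tree, m.polygyny_index, m.polyandry_index, m.queen_dominance,
             m.male_dominance, ";".join(map(str, m.males_per_queen)),
             m.n_workers) for m in per_tree]
    return pd.DataFrame(rows, columns=[
        "tree", "polygyny_index", "polyandry_index", "queen_dominance",
        "male_dominance", "males_per_queen", "n_workers"])


def species_summary(per_tree: list[ColonyMetrics]) -> pd.DataFrame:
    """Species-level mean +/- SE of each index over trees (males per queen
    over qualifying queens)."""
    def mse(x):
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            return (float("nan"), float("nan"), 0)
        se = (float(np.std(x, ddof=1) / np.sqrt(x.size))
              if x.size > 1 else float("nan"))
        return (float(np.mean(x)), se, x.size)

    rows = []
    for name, vals in [
        ("polygyny_index", [m.polygyny_index for m in per_tree]),
        ("polyandry_index", [m.polyandry_index for m in per_tree]),
        ("queen_dominance", [m.queen_dominance for m in per_tree]),
        ("male_dominance", [m.male_dominance for m in per_tree]),
        ("males_per_queen", [v for m in per_tree for v in m.males_per_queen]),
    ]:
        mean, se, n = mse(vals)
        rows.append((name, mean, se, n))
    return pd.DataFrame(rows, columns=["metric", "mean", "se", "n"])


@dataclass
class QueenKinshipTable:
    """Sibling vs non-sibling counts for inferred-queen pairs by stratum."""

    related_within: int
    unrelated_within: int
    related_between: int
    unrelated_between: int
    pair_classes: pd.DataFrame  # queen1, queen2, same_tree, relation

    @property
    def proportion_within(self) -> float:
        d = self.related_within + self.unrelated_within
        return self.related_within / d if d else float("nan")

    @property
    def proportion_between(self) -> float:
        d = self.related_between + self.unrelated_between
        return self.related_between / d if d else float("nan")

    def contingency(self) -> np.ndarray:
        """2x2 [[related-within, unrelated-within],
        [related-between, unrelated-between]]."""
        return np.array([[self.related_within, self.unrelated_within],
                         [self.related_between, self.unrelated_between]])


def classify_queen_pairs(config: SibshipConfig,
                         mothers: GenotypeMatrix) -> pd.DataFrame:
    """Full-sib / half-sib / unrelated label for each queen pair.

    Same maternal and paternal family -> full-sib; same maternal family
    only -> half-sib; different maternal families -> unrelated.
    """
    rows = []
    for a, b in combinations(range(mothers.n_individuals), 2):
        ia, ja = config.family_of(mothers.ids[a])
        ib, jb = config.family_of(mothers.ids[b])
        if ia == ib:
            rel = "full-sib" if ja == jb else "half-sib"
        else:
            rel = "unrelated"
        rows.append((mothers.ids[a], mothers.ids[b],
                     mothers.tree[a] == mothers.tree[b], rel))
    return pd.DataFrame(rows, columns=["queen1", "queen2", "same_tree",
                                       "relation"])


def queen_kinship(mothers: GenotypeMatrix, freqs: AlleleFrequencies,
                  err: ErrorModel | None = None,
                  candidate: CandidateQueen | None = None,
                  search: str = "anneal", seed: int = 0) -> QueenKinshipTable:
    """Classify inferred-queen pairs as siblings or not, by tree stratum.

    The pooled mothers are treated as one diploid offspring set of unknown
    diploid parents (diplodiploid reconstruction) and each pair is labelled
    full-sibling, half-sibling, or unrelated from the resulting nested
    partition; "related" pools full- and half-siblings.
    """
    if mothers.n_individuals < 2:
        return QueenKinshipTable(0, 0, 0, 0, pd.DataFrame(
            columns=["queen1", "queen2", "same_tree", "relation"]))
    cfg = reconstruct(mothers, freqs, err or ErrorModel(),
                      candidate=candidate, search=search, seed=seed,
                      ploidy="diplodiploid")
    pairs = classify_queen_pairs(cfg, mothers)
    related = pairs["relation"].isin(["full-sib", "half-sib"])
    within = pairs["same_tree"]
    return QueenKinshipTable(
        related_within=int((related & within).sum()),
        unrelated_within=int((~related & within).sum()),
        related_between=int((related & ~within).sum()),
        unrelated_between=int((~related & ~within).sum()),
        pair_classes=pairs,
    )


def kinship_table(table: QueenKinshipTable) -> pd.DataFrame:
    return pd.DataFrame(
        [("within-tree", table.related_within, table.unrelated_within,
          table.proportion_within),
         ("between-tree", table.related_between, table.unrelated_between,
          table.proportion_between)],
        columns=["stratum", "related", "unrelated", "proportion_related"])
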