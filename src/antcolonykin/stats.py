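"""Statistical comparisons for relatedness summaries and colony metrics.

The battery mirrors a standard field-study analysis plan: species are
compared by ANOVA with Tukey's HSD post hoc when the metric is roughly
normal, or by Kruskal-Wallis with Nemenyi post hoc otherwise (the choice is
the caller's, recorded in the report, not an automated normality gate);
between-tree relatedness is tested against zero with a one-tailed t test;
tree-size effects are screened by Pearson or Spearman correlation and by
ANCOVA (metric ~ species + height, no interaction); and within- versus
between-tree queen sibship proportions are compared by Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestReport:
    test: str
    grouping: str
    statistic: float
    p_value: float
    post_hoc: pd.DataFrame | None = None  # columns: group1, group2, p
    transform: str = "none"
    sampling_unit: str = "tree"

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _split_groups(values, labels) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    return {g: values[labels == g] for g in dict.fromkeys(labels)}


def nemenyi_pairwise(values, labels) -> pd.DataFrame:
    """All-pairs Nemenyi test on pooled ranks, chi-square approximation.

    Observations are ranked jointly (mid-ranks for ties); for groups i, j
    the statistic (Rbar_i - Rbar_j)^2 / [ (N(N+1)/12 - T)(1/n_i + 1/n_j) ]
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) is referred to a
    chi-square distribution with k - 1 degrees of freedom.
    """
    groups = _split_groups(values, labels)
    k = len(groups)
    pooled = np.concatenate(list(groups.values()))
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    offsets = np.cumsum([0] + [v.size for v in groups.values()])
    mean_rank = {g: float(np.mean(ranks[a:b]))
                 for g, a, b in zip(groups, offsets, offsets[1:])}
    rows = []
    for g1, g2 in combinations(sorted(groups, key=str), 2):
        n1, n2 = groups[g1].size, groups[g2].size
        var = (n_tot * (n_tot + 1) / 12.0 - tie) * (1.0 / n1 + 1.0 / n2)
        chi2 = (mean_rank[g1] - mean_rank[g2]) ** 2 / var
        p = float(sps.chi2.sf(chi2, k - 1))
        rows.append((g1, g2, p))
    return pd.DataFrame(rows, columns=["group1", "group2", "p"])


def tukey_pairwise(values, labels) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float),
                            np.asarray(labels))
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    return frame.rename(columns={"p-adj": "p"})[["group1", "group2", "p"]]


def compare_species(values, labels, family: str = "kwt+nemenyi",
                    metric: str = "metric") -> TestReport:
    """Omnibus species comparison with the matching post hoc battery."""
    groups = _split_groups(values, labels)
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        raise ValueError("constant data: omnibus variance is degenerate")
    if family == "anova+tukey":
        stat, p = sps.f_oneway(*groups.values())
        if stat < 0.0:  # catastrophic cancellation at F = 0 exactly
            stat, p = 0.0, 1.0
        post = tukey_pairwise(values, labels)
        name = "ANOVA"
    elif family == "kwt+nemenyi":
        stat, p = sps.kruskal(*groups.values())
        post = nemenyi_pairwise(values, labels)
        name = "Kruskal-Wallis"
    else:
        raise ValueError(f"unknown test family {family!r}")
    return TestReport(test=name, grouping=metric, statistic=float(stat),
                      p_value=float(p), post_hoc=post)


def ttest_vs_zero(values, metric: str = "between-tree relatedness",
                  sampling_unit: str = "tree-pair") -> TestReport:
    """One-tailed (greater-than-zero) one-sample t test.

    With all values exactly zero the statistic is 0 and the one-tailed p
    is 0.5 (the symmetric-null boundary).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    res = sps.ttest_1samp(values, 0.0, alternative="greater")
    stat = float(res.statistic)
    p = 0.5 if np.isnan(stat) or stat == 0.0 else float(res.pvalue)
    return TestReport(test="one-tailed t vs 0", grouping=metric,
                      statistic=0.0 if np.isnan(stat) else stat, p_value=p,
                      sampling_unit=sampling_unit)


def tree_size_effects(metric_values, sizes, species,
                      method: str = "pearson", sqrt_transform: bool = False,
                      metric: str = "metric") -> list[TestReport]:
    """Correlation with tree size, plus ANCOVA metric ~ species + size.

    Returns two reports: the overall correlation (Pearson on raw or
    square-root-transformed values, or Spearman) and the ANCOVA covariate
    effect (type-II sum of squares, no interaction term).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(sizes, dtype=float)
    sp_lab = np.asarray(species)
    if not (y.shape == x.shape == sp_lab.shape):
        raise ValueError("metric, sizes and species must have equal length")
    if np.any(x <= 0):
        raise ValueError("tree sizes must be positive")
    transform = "none"
    yy = y
    if sqrt_transform:
        yy = np.sqrt(y)
        transform = "sqrt"
    if method == "pearson":
        stat, p = sps.pearsonr(yy, x)
        name = "Pearson correlation"
    elif method == "spearman":
        stat, p = sps.spearmanr(yy, x)
        name = "Spearman correlation"
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = TestReport(test=name, grouping=f"{metric} ~ size",
                      statistic=float(stat), p_value=float(p),
                      transform=transform)

    df = pd.DataFrame({"y": yy, "size": x, "species": sp_lab})
    fit = smf.ols("y ~ C(species) + size", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ancova = TestReport(
        test="ANCOVA", grouping=f"{metric} ~ species + size",
        statistic=float(table.loc["size", "F"]),
        p_value=float(table.loc["size", "PR(>F)"]),
        transform=transform)
    return [corr, ancova]


def fisher_queen_sibship(table) -> TestReport:
    """Two-sided Fisher's exact test on the queen-sibship 2x2 table.

    ``table`` is [[related-within, unrelated-within],
    [related-between, unrelated-between]] or a QueenKinshipTable.
    """
    if hasattr(table, "contingency"):
        table = table.contingency()
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if table.sum() < 1:
        raise ValueError("all-zero contingency table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestReport(test="Fisher exact", grouping="queen sibship",
                      statistic=float(odds), p_value=float(p),
                      sampling_unit="queen-pair")


def report_frame(reports: list[TestReport]) -> pd.DataFrame:
    rows = [(r.test, r.grouping, r.statistic, r.p_value, r.transform,
             r.sampling_unit) for r in reports]
    return pd.DataFrame(rows, columns=["test", "grouping", "statistic",
                                       "p_value", "transform",
                                       "sampling_unit"])
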