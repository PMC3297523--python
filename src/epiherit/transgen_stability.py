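"""Transgenerational stability statistics.

Four complementary views of whether expression/methylation differences are
stable from parents to offspring:

* **Top-K fold-change concordance** — rank features by |log2FC| in each
  generation, intersect the two top-K sets (K = 1000 by default) and
  correlate the signed log2FC of parents vs offspring on the intersection.
* **Within- vs between-family correlation** — for each parental array,
  compare its mean genome-wide Pearson correlation with its own family's
  offspring pools against other families' pools (same breed by default);
  a paired t-test across parents asks whether own-family correlations are
  systematically higher.
* **Overlap fraction** — of the features significant in the parents, the
  fraction also significant in the offspring.
* **Directional hypermethylation bias** — among promoters differentially
  methylated in both generations, a 1-df goodness-of-fit chi-square of the
  hyper/hypo split against a 50:50 null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_dm_stats import ModeratedTestFit


@dataclass
class ConcordanceResult:
    k: int | None
    feature_ids: list
    n_selected: int
    r: float  # Pearson r of parent vs offspring log2FC; NaN if undefined
    degenerate: bool = False


@dataclass
class FamilyCorrelationResult:
    per_parent: pd.DataFrame  # parent sample, within mean r, between mean r, diff
    mean_difference: float
    sem: float
    t: float
    df: int
    p: float


@dataclass
class BiasTestResult:
    n_hyper: int
    n_hypo: int
    fraction_hyper: float
    chi2: float
    p: float


def _rank_top(fit: ModeratedTestFit, k: int | None) -> pd.Index:
    tab = fit.table
    order = tab.sort_values(
        ["log2fc", "p"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="stable",
    )
    if k is None:
        return order.index
    return order.index[:k]


def topk_concordance(
    fit_parents: ModeratedTestFit, fit_offspring: ModeratedTestFit, k: int | None = 1000
) -> ConcordanceResult:
    """Cross-generation fold-change concordance on the shared top-K.

    Both generations are ranked by |log2FC| descending (ties broken by
    smaller raw p); the intersection of the two top-K sets is correlated on
    signed log2FC.  ``k=None`` uses every shared feature, in which case r is
    the plain cross-generation fold-change correlation.  Fewer than 3 shared
    features leaves r undefined (NaN, flagged degenerate).
    """
    top_p = set(_rank_top(fit_parents, k))
    top_o = set(_rank_top(fit_offspring, k))
    shared = sorted(top_p & top_o)
    if len(shared) < 3:
        return ConcordanceResult(k=k, feature_ids=shared, n_selected=len(shared),
                                 r=float("nan"), degenerate=True)
    x = fit_parents.table.loc[shared, "log2fc"].to_numpy()
    y = fit_offspring.table.loc[shared, "log2fc"].to_numpy()
    r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(k=k, feature_ids=shared, n_selected=len(shared), r=r)


def family_correlation_test(
    parent_matrix: pd.DataFrame,
    offspring_matrix: pd.DataFrame,
    design: pd.DataFrame,
    between_scope: str = "breed",
) -> FamilyCorrelationResult:
    """Do parents correlate more with their own offspring than with others'?

    For every parental array, Pearson correlations of its full feature vector
    against each offspring pool are averaged within the parent's own family
    and within the comparison pools (same-breed other families for
    ``between_scope='breed'``, all other families for ``'all'``); the paired
    differences are tested against zero with a one-sample t across parents.
    Raw correlation coefficients are averaged (no Fisher transform), matching
    how such global-profile comparisons are usually reported.
    """
    if between_scope not in ("breed", "all"):
        raise ValueError("between_scope must be 'breed' or 'all'")
    meta = design.set_index("sample_id")
    rows = []
    for parent in parent_matrix.columns:
        pvec = parent_matrix[parent].to_numpy(dtype=float)
        if np.std(pvec) == 0:
            raise ValueError(f"parent {parent} has a constant feature vector")
        own, other = [], []
        for pool in offspring_matrix.columns:
            r = float(np.corrcoef(pvec, offspring_matrix[pool].to_numpy(dtype=float))[0, 1])
            same_family = meta.loc[pool, "family"] == meta.loc[parent, "family"]
            same_breed = meta.loc[pool, "breed"] == meta.loc[parent, "breed"]
            if same_family:
                own.append(r)
            elif between_scope == "all" or same_breed:
                other.append(r)
        if not own or not other:
            raise ValueError(f"parent {parent} lacks own-family or comparison pools")
        rows.append(
            {
                "parent": parent,
                "within_mean_r": np.mean(own),
                "between_mean_r": np.mean(other),
            }
        )
    per_parent = pd.DataFrame(rows)
    per_parent["difference"] = per_parent["within_mean_r"] - per_parent["between_mean_r"]
    d = per_parent["difference"].to_numpy()
    n = len(d)
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    sem = sd / np.sqrt(n)
    if sd == 0:
        t, p = 0.0, 1.0
    else:
        t = mean_diff / sem
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return FamilyCorrelationResult(
        per_parent=per_parent, mean_difference=mean_diff, sem=float(sem),
        t=float(t), df=n - 1, p=p,
    )


def hyper_bias_test(n_hyper: int, n_hypo: int) -> BiasTestResult:
    """1-df goodness-of-fit chi-square of the hyper/hypo split vs 50:50.

    chi2 = sum over the two classes of (obs - total/2)^2 / (total/2), with
    the p-value from the upper tail of a chi-square on 1 df.  No continuity
    correction is applied.
    """
    if n_hyper < 0 or n_hypo < 0:
        raise ValueError("counts must be non-negative")
    total = n_hyper + n_hypo
    if total == 0:
        raise ValueError("hyper_bias_test needs at least one promoter")
    expected = total / 2.0
    chi2 = (n_hyper - expected) ** 2 / expected + (n_hypo - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return BiasTestResult(
        n_hyper=int(n_hyper),
        n_hypo=int(n_hypo),
        fraction_hyper=n_hyper / total,
        chi2=float(chi2),
        p=p,
    )


def bias_from_calls(calls_parents: pd.DataFrame, calls_offspring: pd.DataFrame) -> BiasTestResult:
    """Bias test restricted to promoters significant in both generations,
    using the parental direction for classification."""
    both = calls_parents.index[calls_parents["significant"]].intersection(
        calls_offspring.index[calls_offspring["significant"]]
    )
    if len(both) == 0:
        raise ValueError("no promoter is significant in both generations")
    directions = calls_parents.loc[both, "direction"]
    return hyper_bias_test(int((directions > 0).sum()), int((directions < 0).sum()))


def overlap_fraction(calls_parents, calls_offspring) -> tuple[float, int, int]:
    """|A ∩ B| / |A| with A the parent-significant and B the
    offspring-significant feature sets; returns (fraction, n_overlap, n_a)."""
    a, b = set(calls_parents), set(calls_offspring)
    if not a:
        raise ValueError("the parental significant set is empty")
    inter = len(a & b)
    return inter / len(a), inter, len(a)
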