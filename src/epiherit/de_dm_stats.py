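"""Differential expression / differential methylation calling.

Two-group comparisons are tested feature-by-feature with an empirical-Bayes
moderated t-statistic: per-feature pooled residual variances s_g^2 (d degrees
of freedom each) are shrunk toward a prior variance s0^2 with prior degrees of
freedom d0, both estimated from the data by matching moments of log s_g^2 to
a scaled F distribution.  The moderated statistic

    t_g = (mean_2 - mean_1) / sqrt( s~_g^2 (1/n1 + 1/n2) ),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

is referred to a t distribution on d0 + d degrees of freedom; p-values are
two-sided and adjusted by Benjamini-Hochberg step-up FDR.

Sign convention: ``log2fc`` is group2 minus group1 mean; throughout the
pipeline group2 is the domesticated breed, so positive values mean higher
expression (or methylation) in the domestic line.

Probe-level methylation results are reduced to one call per promoter by
taking each promoter's most significant probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

FDR_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior (method of moments on log s^2)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing from +inf to 0 on (0, inf), so a unique
    root exists for any y > 0.
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior.

    Moment matching on z = log(s^2): under the hierarchical model
    z - digamma(d/2) + log(d/2) has mean log(s0^2) - digamma(d0/2) - log(2/d0)
    and excess variance trigamma(d0/2) over trigamma(d/2).

    Returns d0 = inf when the observed spread of log-variances does not
    exceed the sampling spread (complete shrinkage to a common variance) and
    d0 = 0 when fewer than two positive variances are available (no
    shrinkage possible).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return 0.0, float("nan")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if evar < 1e-12:
        # log-variances exactly constant: the common variance is the prior
        return float("inf"), float(np.exp(np.mean(z)))
    if rhs <= 0:
        return float("inf"), float(np.exp(emean))
    half_d0 = _trigamma_inverse(rhs)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


# ---------------------------------------------------------------------------
# moderated t


@dataclass
class ModeratedTestFit:
    """Result of a two-group moderated-t fit.

    ``table`` is indexed by feature id with columns ``mean1``, ``mean2``,
    ``log2fc`` (mean2 - mean1), ``s2`` (pooled residual variance), ``t``,
    ``p``, ``p_adj``.  ``d0``/``s0_sq`` are the shared prior degrees of
    freedom and variance; ``df_resid`` the per-feature residual df.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    d0: float
    s0_sq: float
    df_resid: float
    df_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.df_total = self.d0 + self.df_resid


def fit_moderated_t(
    matrix: pd.DataFrame, labels: pd.Series, groups: tuple[str, str] | None = None
) -> ModeratedTestFit:
    """Fit the two-group empirical-Bayes moderated t per feature.

    Parameters
    ----------
    matrix : DataFrame, features x samples
        log2-scale measurements.
    labels : Series, sample -> group
        Must take exactly two values on the columns of ``matrix``; samples
        with labels outside ``groups`` are ignored.
    groups : optional (group1, group2)
        Order fixes the sign of ``log2fc = mean(group2) - mean(group1)``.
        Defaults to the sorted pair of observed labels.

    Each group needs at least two samples so a residual variance exists.
    """
    labels = labels.reindex(matrix.columns)
    observed = sorted(labels.dropna().unique())
    if groups is None:
        if len(observed) != 2:
            raise ValueError(f"expected exactly two groups, got {observed}")
        groups = (observed[0], observed[1])
    g1, g2 = groups
    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each contrasted group needs >=2 samples (got {g1}:{n1}, {g2}:{n2})"
        )
    x1 = matrix[cols1].to_numpy(dtype=float)
    x2 = matrix[cols2].to_numpy(dtype=float)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    df = float(n1 + n2 - 2)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df

    d0, s0_sq = estimate_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

    log2fc = mean2 - mean1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    df_total = d0 + df
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "mean1": mean1,
            "mean2": mean2,
            "log2fc": log2fc,
            "s2": s2,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=matrix.index,
    )
    return ModeratedTestFit(table=table, groups=(g1, g2), d0=d0, s0_sq=s0_sq, df_resid=df)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj at rank i is min_{j >= i} (n/j) p_(j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_significant(fit: ModeratedTestFit, fdr: float = FDR_DEFAULT) -> list:
    """Feature ids with BH-adjusted p below ``fdr``."""
    return list(fit.table.index[fit.table["p_adj"] < fdr])


# ---------------------------------------------------------------------------
# promoter-level aggregation


def aggregate_promoters(
    fit: ModeratedTestFit, probe_table: pd.DataFrame, fdr: float = FDR_DEFAULT
) -> pd.DataFrame:
    """Reduce probe-level results to one call per promoter.

    The best probe of a promoter is the one with minimal raw p (ties broken
    by larger |log2fc|, then smaller start coordinate).  A promoter is
    significant iff its best probe's BH-adjusted p (adjusted over all probes)
    is below ``fdr``; the direction is the sign of the best probe's log2fc
    (+1 = hypermethylated in the domestic breed under the pipeline's sign
    convention).

    Returns a DataFrame indexed by ``promoter_id`` with columns ``probe_id``,
    ``log2fc``, ``t``, ``p``, ``p_adj``, ``significant``, ``direction``.
    """
    meta = probe_table.set_index("probe_id")[["promoter_id", "start"]]
    joined = fit.table.join(meta, how="inner")
    if joined["promoter_id"].isna().any() or len(joined) == 0:
        raise ValueError("every tested probe must map to a promoter")
    joined = joined.reset_index(names="probe_id")
    joined["_abs_fc"] = -joined["log2fc"].abs()
    joined = joined.sort_values(
        ["promoter_id", "p", "_abs_fc", "start"], kind="stable"
    )
    best = joined.groupby("promoter_id", sort=True).head(1).set_index("promoter_id")
    out = best[["probe_id", "log2fc", "t", "p", "p_adj"]].copy()
    out["significant"] = out["p_adj"] < fdr
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out
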