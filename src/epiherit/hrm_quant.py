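"""Methylation-sensitive high-resolution melting (MS-HRM) quantification.

Bisulfite conversion turns unmethylated cytosines into uracil, so amplicons
from unmethylated templates are AT-richer and melt at a lower temperature
than amplicons from methylated templates.  Quantification proceeds by:

1. normalizing each melting curve between a pre-melt and a post-melt
   baseline (linear fits in two temperature windows; normalized fluorescence
   runs from ~100 down to ~0);
2. locating T_md, the temperature at which the fully methylated (positive)
   and fully unmethylated (negative) control curves differ the most;
3. reading each sample's normalized fluorescence at T_md and comparing
   groups with a Welch two-sample t-test;
4. optionally converting intensities at T_md to percent methylation by
   piecewise-linear interpolation against a calibration series of known
   methylated/unmethylated mixtures (0/25/50/75/100% in the usual assay).

Curves are (temperature, fluorescence) vectors on a strictly increasing
common grid; technical replicates should be averaged into one curve per
sample before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: default width (degC) of the pre- and post-melt baseline windows
BASELINE_WINDOW = 1.5


@dataclass
class HRMResult:
    t_md: float
    intensities: pd.Series  # per-sample normalized fluorescence at T_md
    group_means: dict
    t: float
    df: float
    p: float
    degenerate: bool = False
    fractions: pd.Series | None = None


def _check_grid(temps: np.ndarray) -> np.ndarray:
    temps = np.asarray(temps, dtype=float)
    if temps.size < 10:
        raise ValueError("melting curves need at least 10 temperature points")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    return temps


def normalize_curve(
    temps,
    fluor,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Two-baseline normalization of a melting curve.

    Straight lines are fitted to the fluorescence inside the pre-melt and
    post-melt windows (defaults: first and last 1.5 degC of the grid); the
    normalized curve is 100 * (F - post) / (pre - post), clipped to [0, 100].
    Affine transforms a*F + b of the input normalize to the identical result.
    """
    temps = _check_grid(temps)
    f = np.asarray(fluor, dtype=float)
    if f.shape != temps.shape:
        raise ValueError("temperature and fluorescence vectors differ in length")
    if pre_window is None:
        pre_window = (temps[0], temps[0] + BASELINE_WINDOW)
    if post_window is None:
        post_window = (temps[-1] - BASELINE_WINDOW, temps[-1])
    if not pre_window[1] <= post_window[0]:
        raise ValueError("pre-melt window must precede the post-melt window")

    def fit_line(window):
        m = (temps >= window[0]) & (temps <= window[1])
        if m.sum() < 2 or np.ptp(temps[m]) == 0:
            raise ValueError(f"degenerate baseline window {window}")
        slope, intercept = np.polyfit(temps[m], f[m], 1)
        return slope * temps + intercept

    pre = fit_line(pre_window)
    post = fit_line(post_window)
    span = pre - post
    if np.any(np.abs(span) < 1e-12):
        raise ValueError("pre- and post-melt baselines coincide (zero spread)")
    return np.clip(100.0 * (f - post) / span, 0.0, 100.0)


def find_tmd(temps, pos_norm, neg_norm) -> tuple[float, bool]:
    """Temperature of maximal |positive - negative| control difference.

    Both curves must be normalized on the same grid.  Ties resolve to the
    lowest such temperature.  Returns (T_md, degenerate); degenerate is True
    when the two controls are identical everywhere (T_md then defaults to
    the first grid point and is meaningless).
    """
    temps = _check_grid(temps)
    diff = np.abs(np.asarray(pos_norm, dtype=float) - np.asarray(neg_norm, dtype=float))
    if diff.shape != temps.shape:
        raise ValueError("curves and grid differ in length")
    if np.all(diff == 0):
        return float(temps[0]), True
    return float(temps[np.argmax(diff)]), False  # argmax takes the first maximum


def intensity_at(temps, curve, t: float) -> float:
    """Curve value at temperature t (linear interpolation on the grid)."""
    temps = _check_grid(temps)
    return float(np.interp(t, temps, np.asarray(curve, dtype=float)))


def group_difference(
    temps,
    curves: pd.DataFrame,
    groups: pd.Series,
    t_md: float,
    degenerate: bool = False,
) -> HRMResult:
    """Welch two-sample t-test of normalized intensities at T_md.

    ``curves`` holds one normalized curve per column (samples); ``groups``
    maps sample name to one of exactly two group labels.  Each group needs
    at least two samples.
    """
    temps = _check_grid(temps)
    groups = groups.reindex(curves.columns)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    intensities = pd.Series(
        {c: intensity_at(temps, curves[c].to_numpy(), t_md) for c in curves.columns},
        name="intensity_at_tmd",
    )
    g1 = intensities[groups == labels[0]]
    g2 = intensities[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")
    if np.allclose(g1.var(ddof=1), 0) and np.allclose(g2.var(ddof=1), 0):
        t, p = (0.0, 1.0) if np.isclose(g1.mean(), g2.mean()) else (np.inf, 0.0)
        df = float(len(g1) + len(g2) - 2)
    else:
        res = stats.ttest_ind(g1, g2, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return HRMResult(
        t_md=float(t_md),
        intensities=intensities,
        group_means={labels[0]: float(g1.mean()), labels[1]: float(g2.mean())},
        t=t,
        df=df,
        p=p,
        degenerate=degenerate,
    )


def estimate_fraction(intensity: float, calib_fractions, calib_intensities) -> tuple[float, bool]:
    """Percent methylation by piecewise-linear calibration interpolation.

    ``calib_fractions`` are the known mixture percentages (must include 0 and
    100); ``calib_intensities`` the normalized intensities at T_md of the
    corresponding calibration curves, strictly monotone in fraction.
    Intensities outside the calibrated range clip to [0, 100] and are
    flagged.  Returns (percent, out_of_range).
    """
    fr = np.asarray(calib_fractions, dtype=float)
    ci = np.asarray(calib_intensities, dtype=float)
    if fr.size != ci.size or fr.size < 2:
        raise ValueError("calibration needs >=2 matching fraction/intensity pairs")
    order = np.argsort(fr)
    fr, ci = fr[order], ci[order]
    if np.unique(fr).size != fr.size:
        raise ValueError("calibration fractions must be unique")
    if not (fr[0] == 0.0 and fr[-1] == 100.0):
        raise ValueError("calibration must span 0% and 100%")
    d = np.diff(ci)
    if np.all(d > 0):
        pass
    elif np.all(d < 0):
        fr, ci = fr[::-1], ci[::-1]
    else:
        raise ValueError("calibration intensities must be strictly monotone in fraction")
    out_of_range = bool(intensity < ci[0] or intensity > ci[-1])
    pct = float(np.interp(intensity, ci, fr))
    return float(np.clip(pct, 0.0, 100.0)), out_of_range


def average_replicates(curves: pd.DataFrame, sample_of: pd.Series) -> pd.DataFrame:
    """Average technical-replicate columns into one curve per sample
    (assays are typically run in triplicate)."""
    mapping = sample_of.reindex(curves.columns)
    return curves.T.groupby(mapping).mean().T
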