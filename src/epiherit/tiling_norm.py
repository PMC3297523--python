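"""Two-colour MeDIP tiling-array preprocessing.

Arrays carry, per probe, an M-value (log2 ratio of the methylation-enriched
channel over the total-input reference channel) and an A-value (average log2
intensity of the two channels).  Preprocessing is two-step:

1. within each array, the M-values are centred by subtracting a one-step
   Tukey-biweight location estimate, removing array-wide dye/enrichment bias
   robustly against the minority of truly methylated probes;
2. between arrays, the A-values are quantile-normalized (each array's sorted
   A replaced by the across-array mean of sorted A) so that intensity
   distributions are comparable; M-values are left untouched by this step.

Probe tables are pandas DataFrames with columns ``probe_id``, ``chrom``,
``start``, ``end``, ``promoter_id`` followed by per-sample ``M_<sample>`` and
``A_<sample>`` columns (0-based half-open coordinates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: default biweight tuning constant (units of MAD)
BIWEIGHT_C = 5.0
#: floor added to c*MAD so constant data does not divide by zero
BIWEIGHT_EPS = 1e-4

PROBE_META_COLS = ["probe_id", "chrom", "start", "end", "promoter_id"]


def m_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-sample M-value columns of a probe table."""
    return [c for c in table.columns if c.startswith("M_")]


def a_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-sample A-value columns of a probe table."""
    return [c for c in table.columns if c.startswith("A_")]


def tukey_biweight_location(
    values, c: float = BIWEIGHT_C, eps: float = BIWEIGHT_EPS
) -> float:
    """One-step Tukey-biweight location estimate.

    Starting from the median ``m``, each point gets weight
    ``w_i = (1 - u_i^2)^2`` for ``|u_i| < 1`` (else 0), with
    ``u_i = (x_i - m) / (c * MAD + eps)``, and the weighted mean is returned.
    One step only; the estimate is not iterated to convergence.

    Parameters
    ----------
    values : array-like
        At least one finite value.
    c : float
        Tuning constant in units of the median absolute deviation.
    eps : float
        Additive floor on the scale, so constant vectors are handled.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("tukey_biweight_location requires at least one finite value")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    # the median itself always has u=0, w=1, so the denominator is positive
    return float(np.sum(w * x) / np.sum(w))


def normalize_within(table: pd.DataFrame, c: float = BIWEIGHT_C) -> pd.DataFrame:
    """Centre each array's M-values at its one-step biweight location.

    Exactly shift-equivariant, hence idempotent: re-applying the operation
    leaves the table unchanged, and the biweight of each centred array is 0.
    Returns a new DataFrame; A-values and probe metadata are untouched.
    """
    out = table.copy()
    for col in m_columns(table):
        out[col] = table[col] - tukey_biweight_location(table[col].to_numpy(), c=c)
    return out


def normalize_between(table: pd.DataFrame) -> pd.DataFrame:
    """A-quantile normalization across arrays.

    Each array's sorted A-vector is replaced by the mean of the sorted
    A-vectors over all arrays; ties within an array receive the mean target
    value of their tied ranks (rank-average policy).  M-values are returned
    bit-identical.  Requires at least two arrays of equal probe count (the
    shared table layout enforces the latter).
    """
    cols = a_columns(table)
    if len(cols) < 2:
        raise ValueError("normalize_between requires at least two arrays")
    A = table[cols].to_numpy(dtype=float)
    target = np.sort(A, axis=0).mean(axis=1)  # mean of sorted A across arrays
    out = table.copy()
    n = A.shape[0]
    grid = np.arange(1, n + 1, dtype=float)
    for j, col in enumerate(cols):
        ranks = rankdata(A[:, j], method="average")
        # fractional (tied) ranks interpolate linearly between target quantiles
        out[col] = np.interp(ranks, grid, target)
    return out


def normalize(table: pd.DataFrame, c: float = BIWEIGHT_C) -> pd.DataFrame:
    """Full preprocessing: within-array M centring, then between-array
    A-quantile normalization."""
    return normalize_between(normalize_within(table, c=c))
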