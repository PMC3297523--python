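"""Permutation test for gene proximity to selective sweeps.

Given a set of gene intervals, a set of sweep intervals, and the covered
genome (regions eligible for sweep detection and random placement), the test
asks whether more genes lie within a proximity window w (50 kb by default) of
a sweep than expected by chance.  The null is built by repeatedly redrawing
each gene interval — same length, uniform over every covered position that
admits it wholly — and recounting; the empirical p-value uses the add-one
rule p = (1 + #{null >= observed}) / (n_sets + 1), so p is never zero.

Interval frames are pandas DataFrames with columns ``chrom``, ``start``,
``end`` (0-based half-open) and optionally ``name``; BED I/O helpers are
provided.  Distance between intervals is the end-to-start gap on the same
chromosome (overlapping or touching intervals have distance 0); intervals on
different chromosomes are infinitely distant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PROXIMITY_WINDOW = 50_000
N_SETS_DEFAULT = 1000


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (chrom, start, end[, name, ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"iv{i}" for i in range(len(out))]
    out["score"] = 0
    out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        Path(path), sep="\t", header=False, index=False
    )


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p: float
    n_sets: int
    window: int
    seed: int | None
    n_query: int
    n_dropped: int = 0


class _ProximityIndex:
    """Merged sweep-proximity zones per chromosome, for O(log n) lookups.

    A query [qs, qe) is within distance w of some sweep [ss, se) iff
    qe >= ss - w and qs <= se + w; with zones stored as the half-open
    [ss - w - 1, se + w + 1) this is ordinary strict-overlap testing.
    """

    def __init__(self, sweeps: pd.DataFrame, window: int):
        self.zones: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in sweeps.groupby("chrom", sort=False):
            lo = (grp["start"].to_numpy(dtype=np.int64) - window - 1)
            hi = (grp["end"].to_numpy(dtype=np.int64) + window + 1)
            order = np.argsort(lo)
            lo, hi = lo[order], hi[order]
            # merge overlapping zones so running max(hi) is just hi
            m_lo, m_hi = [lo[0]], [hi[0]]
            for a, b in zip(lo[1:], hi[1:]):
                if a <= m_hi[-1]:
                    m_hi[-1] = max(m_hi[-1], b)
                else:
                    m_lo.append(a)
                    m_hi.append(b)
            self.zones[chrom] = (np.asarray(m_lo), np.asarray(m_hi))

    def is_proximal(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        if chrom not in self.zones:
            return np.zeros(len(qs), dtype=bool)
        lo, hi = self.zones[chrom]
        idx = np.searchsorted(lo, qe, side="left")  # zones with lo < qe
        hit = idx > 0
        hit[hit] = hi[idx[hit] - 1] > qs[hit]
        return hit


def count_proximal(query: pd.DataFrame, sweeps: pd.DataFrame, window: int = PROXIMITY_WINDOW) -> int:
    """Number of query intervals within ``window`` bp of a same-chromosome
    sweep (distance inclusive; overlap counts as distance 0); each query
    interval is counted at most once."""
    if len(query) == 0 or len(sweeps) == 0:
        return 0
    index = _ProximityIndex(sweeps, window)
    total = 0
    for chrom, grp in query.groupby("chrom", sort=False):
        total += int(
            index.is_proximal(
                chrom,
                grp["start"].to_numpy(dtype=np.int64),
                grp["end"].to_numpy(dtype=np.int64),
            ).sum()
        )
    return total


def _placement_tables(query: pd.DataFrame, covered: pd.DataFrame):
    """Per-query admissible-start weights over covered regions.

    Returns (lengths, region_starts, region_chroms, weight matrix) where
    weights[i, r] = number of admissible starts for query i in region r.
    """
    lengths = (query["end"] - query["start"]).to_numpy(dtype=np.int64)
    if np.any(lengths <= 0):
        raise ValueError("query intervals must have positive length")
    r_start = covered["start"].to_numpy(dtype=np.int64)
    r_len = (covered["end"] - covered["start"]).to_numpy(dtype=np.int64)
    weights = np.clip(r_len[None, :] - lengths[:, None] + 1, 0, None)
    if np.any(weights.sum(axis=1) == 0):
        raise ValueError("some query interval is longer than every covered region")
    return lengths, r_start, covered["chrom"].to_numpy(), weights


def permute_intervals(
    query: pd.DataFrame,
    covered: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """One random interval per query interval: same length, start uniform
    over all covered positions admitting the whole interval.  Random
    intervals are placed independently and may overlap each other."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths, r_start, r_chrom, weights = _placement_tables(query, covered)
    n = len(lengths)
    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        w = weights[i]
        probs = w / w.sum()
        r = rng.choice(len(w), p=probs)
        starts[i] = r_start[r] + rng.integers(0, w[r])
        chroms[i] = r_chrom[r]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "name": query["name"].to_numpy() if "name" in query.columns else np.arange(n),
        }
    )


def enrichment_test(
    query: pd.DataFrame,
    sweeps: pd.DataFrame,
    covered: pd.DataFrame,
    window: int = PROXIMITY_WINDOW,
    n_sets: int = N_SETS_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test of sweep proximity.

    Generates ``n_sets`` random interval sets matched in length to the query
    set, counts proximal intervals in each, and reports the add-one empirical
    p-value against the observed count.  The per-query placements across all
    sets are drawn in one vectorised pass; queries are processed in order of
    interval length, so the result is exactly invariant to query input order
    and chromosome relabeling (a placement's law depends only on its length).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = count_proximal(query, sweeps, window)
    null_counts = np.zeros(n_sets, dtype=np.int64)
    if len(query) and len(sweeps):
        index = _ProximityIndex(sweeps, window)
        lengths, r_start, r_chrom, weights = _placement_tables(query, covered)
        n_regions = weights.shape[1]
        order = np.argsort(lengths, kind="stable")
        lengths, weights = lengths[order], weights[order]
        for i in range(len(lengths)):
            w = weights[i]
            ridx = rng.choice(n_regions, size=n_sets, p=w / w.sum())
            offs = rng.integers(0, w[ridx])
            starts = r_start[ridx] + offs
            ends = starts + lengths[i]
            hit = np.zeros(n_sets, dtype=bool)
            for chrom in np.unique(r_chrom[ridx]):
                m = r_chrom[ridx] == chrom
                hit[m] = index.is_proximal(chrom, starts[m], ends[m])
            null_counts += hit
    p = (1.0 + np.sum(null_counts >= observed)) / (n_sets + 1.0)
    return PermutationResult(
        observed=int(observed),
        null_counts=null_counts,
        p=float(p),
        n_sets=int(n_sets),
        window=int(window),
        seed=None if isinstance(seed, np.random.Generator) else seed,
        n_query=len(query),
    )


def interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two same-chromosome half-open intervals (0 if they
    overlap or touch)."""
    (a0, a1), (b0, b1) = a, b
    return max(b0 - a1, a0 - b1, 0)
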