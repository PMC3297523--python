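"""Synthetic data generator with known ground truth.

Emulates a two-generation, two-breed design: a wild ancestor breed (RJF) and
a domesticated breed (WL), two families per breed, two parents per family
assayed individually, and two offspring pools (six same-sex birds each) per
family — 8 parental arrays plus 8 offspring-pool arrays.

Generated layers, all driven by one seed split into named substreams:

* an additive log2 expression model with sparse breed (DE) effects, per-family
  effects, and a heritability knob scaling how much of the parental breed and
  family effects reappears in the offspring pools;
* a promoter tiling-array methylation layer: probes every ~100 bp across a
  window from 7.25 kb upstream to 3.25 kb downstream of each TSS, with
  differential methylation (DM) injected on a contiguous probe sub-window and
  a tunable bias of DM directions toward hypermethylation in the domestic
  breed;
* a multi-chromosome genome with non-overlapping selective-sweep intervals
  and gene placement optionally enriched near sweeps;
* two-state melting curves for methylated/unmethylated amplicons and their
  mixtures, on the 70-90 degC grid in 0.05 degC steps.

Offspring pools are modelled as single arrays whose residual standard
deviation is noise_sd / sqrt(pool size): physical pooling of six birds is
approximated by averaging six independent residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger("epiherit")

#: promoter tiling window relative to the TSS (bp; 0-based half-open-ish span)
PROMOTER_UPSTREAM = 7250
PROMOTER_DOWNSTREAM = 3250
PROBE_SPACING = 100
PROBE_LENGTH = 50
#: proximity window for sweep enrichment (bp)
PROXIMITY_WINDOW = 50_000

WILD_BREED = "RJF"
DOMESTIC_BREED = "WL"

# fixed substream ids: adding a component never perturbs the others
_STREAMS = {
    "truth": 1,
    "genome": 2,
    "expression": 3,
    "methylation": 4,
    "melt": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named component of one dataset."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[name])))


DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("chr1", 300_000_000),
    ("chr2", 250_000_000),
    ("chr3", 200_000_000),
    ("chr4", 150_000_000),
    ("chr5", 75_000_000),
)  # totals 975 Mb, the extent of the covered genome in the sweep analysis


@dataclass
class SimConfig:
    """All knobs of the generator; identical configs give identical data.

    Effect-size units are log2 throughout.  ``heritability`` is the fraction
    of the parental breed and family effects transmitted to offspring-pool
    means (1 = fully heritable, 0 = offspring carry no parental effect).
    ``frac_hyper_in_domestic`` sets the probability that a true-DM promoter
    is hypermethylated in the domestic breed.  ``enrichment_factor``
    multiplies the probability that a truly affected (DE or DM) gene lands
    within 50 kb of a sweep; 1 means uniform placement.
    """

    seed: int = 0
    n_breeds: int = 2
    n_families_per_breed: int = 2
    n_parents_per_family: int = 2
    n_offspring_pools_per_family: int = 2
    pool_size: int = 6
    n_genes: int = 2000
    n_de_genes: int = 300
    n_promoters_tiled: int = 400
    n_dm_promoters: int = 30
    frac_hyper_in_domestic: float = 0.79
    breed_effect_sd: float = 1.0
    family_effect_sd: float = 0.3
    heritability: float = 1.0
    noise_sd: float = 0.5
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_sweeps: int = 149
    sweep_length: int = 40_000
    enrichment_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("breed_effect_sd", "family_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_hyper_in_domestic", "heritability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_promoters_tiled > self.n_genes:
            raise ValueError("n_promoters_tiled cannot exceed n_genes")
        if self.n_dm_promoters > self.n_promoters_tiled:
            raise ValueError("n_dm_promoters cannot exceed n_promoters_tiled")

    @property
    def breeds(self) -> list[str]:
        if self.n_breeds == 2:
            return [WILD_BREED, DOMESTIC_BREED]
        return [f"B{i + 1}" for i in range(self.n_breeds)]

    @property
    def domestic(self) -> str:
        return self.breeds[-1]

    @property
    def genome_length(self) -> int:
        return int(sum(length for _, length in self.genome))


@dataclass
class GroundTruth:
    """Per-feature truth of one simulated dataset.

    ``genes`` is indexed by gene_id with the DE/DM indicators and effects and,
    after genome placement, chromosome/TSS/interval columns.  ``dm_direction``
    is +1 (hyper in domestic) or -1 for true-DM promoters and 0 elsewhere.
    """

    genes: pd.DataFrame
    sweeps: pd.DataFrame | None = None
    covered: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# design


def generate_design(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet: one row per array.

    Parents are single animals (pool_size 1), offspring are same-sex pools.
    With the defaults this is 8 parental arrays + 8 offspring-pool arrays.
    """
    rows = []
    sexes = ["M", "F"]
    for breed in cfg.breeds:
        for fam in range(1, cfg.n_families_per_breed + 1):
            family = f"{breed}_fam{fam}"
            for i in range(cfg.n_parents_per_family):
                sex = sexes[i % 2]
                rows.append(
                    {
                        "sample_id": f"P_{family}_{sex}{i // 2 + 1 if i >= 2 else ''}",
                        "breed": breed,
                        "family": family,
                        "generation": "parent",
                        "sex": sex,
                        "pool_size": 1,
                    }
                )
            for i in range(cfg.n_offspring_pools_per_family):
                sex = sexes[i % 2]
                rows.append(
                    {
                        "sample_id": f"O_{family}_{sex}pool{i // 2 + 1 if i >= 2 else ''}",
                        "breed": breed,
                        "family": family,
                        "generation": "offspring",
                        "sex": sex,
                        "pool_size": cfg.pool_size,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth: which genes carry effects


def make_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw DE/DM indicators, directions and effect sizes.

    DE effects are Normal(0, breed_effect_sd) on a random subset of
    ``n_de_genes`` genes.  DM promoters are a random subset of the tiled
    promoters; each gets direction +1 with probability
    ``frac_hyper_in_domestic`` and magnitude breed_effect_sd * U(0.75, 1.5),
    applied over a contiguous probe sub-window of uniform length 3-20 probes.
    Genome coordinates are filled in later by :func:`generate_sweeps`.
    """
    rng = substream(cfg.seed, "truth")
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["tiled"] = np.arange(n) < cfg.n_promoters_tiled

    de_idx = rng.choice(n, size=cfg.n_de_genes, replace=False)
    genes["is_de"] = False
    genes.iloc[de_idx, genes.columns.get_loc("is_de")] = True
    de_effect = np.zeros(n)
    de_effect[de_idx] = rng.normal(0.0, cfg.breed_effect_sd, size=cfg.n_de_genes)
    genes["de_effect"] = de_effect

    dm_idx = rng.choice(cfg.n_promoters_tiled, size=cfg.n_dm_promoters, replace=False)
    genes["is_dm"] = False
    genes.iloc[dm_idx, genes.columns.get_loc("is_dm")] = True
    direction = np.zeros(n, dtype=int)
    direction[dm_idx] = np.where(
        rng.random(cfg.n_dm_promoters) < cfg.frac_hyper_in_domestic, 1, -1
    )
    genes["dm_direction"] = direction
    dm_effect = np.zeros(n)
    dm_effect[dm_idx] = direction[dm_idx] * cfg.breed_effect_sd * rng.uniform(
        0.75, 1.5, size=cfg.n_dm_promoters
    )
    genes["dm_effect"] = dm_effect

    n_probes = probes_per_promoter()
    win_len = rng.integers(3, 21, size=n)
    win_start = rng.integers(0, n_probes - win_len + 1)
    genes["dm_win_start"] = win_start
    genes["dm_win_len"] = win_len
    return GroundTruth(genes=genes)


def probes_per_promoter() -> int:
    """Number of probes tiling one promoter window (105 at 100 bp spacing)."""
    return (PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM) // PROBE_SPACING


# ---------------------------------------------------------------------------
# genome: sweeps and gene placement


def _covered_frame(cfg: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in cfg.genome],
            "start": 0,
            "end": [length for _, length in cfg.genome],
            "name": [f"covered_{c}" for c, _ in cfg.genome],
        }
    )


def _sample_positions(rng, regions: pd.DataFrame, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions over a set of regions: (chrom index, position)."""
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=np.int64)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("cannot sample from an empty region set")
    offsets = rng.integers(0, total, size=size)
    cum = np.cumsum(lengths)
    ridx = np.searchsorted(cum, offsets, side="right")
    pos = regions["start"].to_numpy()[ridx] + (offsets - (cum[ridx] - lengths[ridx]))
    return ridx, pos


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    pieces = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts, ends = [], []
        for s, e in zip(grp["start"], grp["end"]):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not pieces:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(pieces, ignore_index=True)


def complement_intervals(regions: pd.DataFrame, genome: pd.DataFrame) -> pd.DataFrame:
    """Genome minus ``regions`` (both as chrom/start/end frames)."""
    merged = merge_intervals(regions)
    rows = []
    for _, g in genome.iterrows():
        sub = merged[merged["chrom"] == g["chrom"]]
        pos = g["start"]
        for _, r in sub.sort_values("start").iterrows():
            if r["start"] > pos:
                rows.append({"chrom": g["chrom"], "start": pos, "end": r["start"]})
            pos = max(pos, r["end"])
        if pos < g["end"]:
            rows.append({"chrom": g["chrom"], "start": pos, "end": g["end"]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_sweeps(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Place non-overlapping sweep intervals, then assign gene coordinates.

    Sweeps are ``sweep_length`` bp each, placed uniformly by rejection over
    the genome.  Gene intervals are the promoter window around a TSS; truly
    affected (DE or DM) genes land within 50 kb of a sweep with probability
    min(1, enrichment_factor * p0), where p0 is the uniform-placement
    probability, so enrichment_factor = 1 reduces to uniform placement.

    Mutates ``truth`` in place (gene coordinates, sweeps, covered genome)
    and returns the sweep interval frame.
    """
    rng = substream(cfg.seed, "genome")
    covered = _covered_frame(cfg)
    if cfg.n_sweeps * cfg.sweep_length >= cfg.genome_length:
        raise ValueError("genome too small to pack the requested sweeps")

    chrom_names = covered["chrom"].to_numpy()
    chrom_len = dict(zip(covered["chrom"], covered["end"]))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    sweeps_rows = []
    attempts = 0
    max_attempts = 1000 * max(cfg.n_sweeps, 1) + 1000
    while len(sweeps_rows) < cfg.n_sweeps:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place non-overlapping sweeps (packing too tight)")
        ridx, pos = _sample_positions(rng, covered, 1)
        chrom = chrom_names[ridx[0]]
        start = int(pos[0])
        end = start + cfg.sweep_length
        if end > chrom_len[chrom]:
            continue
        if any(start < e and end > s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        sweeps_rows.append(
            {"chrom": chrom, "start": start, "end": end, "name": f"sweep{len(sweeps_rows):04d}"}
        )
    sweeps = pd.DataFrame(
        sweeps_rows, columns=["chrom", "start", "end", "name"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    genes = truth.genes
    n = len(genes)
    affected = (genes["is_de"] | genes["is_dm"]).to_numpy()
    if len(sweeps) and cfg.enrichment_factor > 1.0 and affected.any():
        zones = merge_intervals(
            sweeps.assign(
                start=(sweeps["start"] - PROXIMITY_WINDOW).clip(lower=0),
                end=sweeps["end"] + PROXIMITY_WINDOW,
            )
        )
        zones["end"] = [
            min(e, chrom_len[c]) for c, e in zip(zones["chrom"], zones["end"])
        ]
        outside = complement_intervals(zones, covered)
        p0 = (zones["end"] - zones["start"]).sum() / cfg.genome_length
        q = min(1.0, cfg.enrichment_factor * p0)
        near = affected & (rng.random(n) < q)
        chrom = np.empty(n, dtype=object)
        tss = np.empty(n, dtype=np.int64)
        for mask, regions in ((near, zones), (affected & ~near, outside)):
            if mask.any():
                ridx, pos = _sample_positions(rng, regions, int(mask.sum()))
                chrom[mask] = regions["chrom"].to_numpy()[ridx]
                tss[mask] = pos
        if (~affected).any():
            ridx, pos = _sample_positions(rng, covered, int((~affected).sum()))
            chrom[~affected] = chrom_names[ridx]
            tss[~affected] = pos
    else:
        ridx, pos = _sample_positions(rng, covered, n)
        chrom = chrom_names[ridx]
        tss = pos.astype(np.int64)

    # promoter window must fit the chromosome; relocate (clamp) if it spills
    lo = PROMOTER_UPSTREAM
    hi = np.array([chrom_len[c] - PROMOTER_DOWNSTREAM for c in chrom])
    clamped = np.clip(tss, lo, hi)
    n_moved = int((clamped != tss).sum())
    if n_moved:
        logger.info("relocated %d promoter windows spilling over chromosome ends", n_moved)
    genes["chrom"] = chrom
    genes["tss"] = clamped
    genes["start"] = clamped - PROMOTER_UPSTREAM
    genes["end"] = clamped + PROMOTER_DOWNSTREAM
    truth.sweeps = sweeps
    truth.covered = covered
    return sweeps


# ---------------------------------------------------------------------------
# expression


def generate_expression(cfg: SimConfig, design: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """log2 expression matrix (genes x samples) under the additive model.

    value = baseline_g + de_effect_g * I(domestic) + family_effect_{g,f}
            + Normal(0, noise_sd), with the breed and family terms scaled by
    ``heritability`` in offspring and the residual sd divided by
    sqrt(pool_size) for pooled arrays.
    """
    if len(truth.genes) != cfg.n_genes:
        raise ValueError("ground truth does not match config dimensions")
    rng = substream(cfg.seed, "expression")
    n = cfg.n_genes
    baseline = rng.normal(8.0, 1.5, size=n)
    families = sorted(design["family"].unique())
    fam_eff = {f: rng.normal(0.0, cfg.family_effect_sd, size=n) for f in families}
    de_effect = truth.genes["de_effect"].to_numpy()

    data = {}
    for _, s in design.iterrows():
        h = 1.0 if s["generation"] == "parent" else cfg.heritability
        mu = baseline + h * (
            de_effect * (s["breed"] == cfg.domestic) + fam_eff[s["family"]]
        )
        sd = cfg.noise_sd / np.sqrt(s["pool_size"])
        data[s["sample_id"]] = mu + rng.normal(0.0, 1.0, size=n) * sd
    return pd.DataFrame(data, index=truth.genes.index.copy())


# ---------------------------------------------------------------------------
# methylation tiling array


def generate_methylation(cfg: SimConfig, design: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Probe-level M/A table for the tiled promoters.

    Each tiled promoter gets a probe every 100 bp across the window from
    7.25 kb upstream to 3.25 kb downstream of its TSS (105 probes of 50 bp).
    True-DM promoters carry their effect on a contiguous probe sub-window;
    a per-array M offset emulates dye/enrichment bias (removed later by
    within-array centring).  Requires gene coordinates, i.e. run
    :func:`generate_sweeps` first.
    """
    if "tss" not in truth.genes.columns:
        raise ValueError("run generate_sweeps first: gene coordinates are missing")
    rng = substream(cfg.seed, "methylation")
    genes = truth.genes[truth.genes["tiled"]]
    n_probes = probes_per_promoter()
    k = np.arange(n_probes)

    rel_start = -PROMOTER_UPSTREAM + k * PROBE_SPACING
    starts = (genes["tss"].to_numpy()[:, None] + rel_start[None, :]).ravel()
    n_rows = len(genes) * n_probes
    table = pd.DataFrame(
        {
            "probe_id": [f"p{i:06d}" for i in range(n_rows)],
            "chrom": np.repeat(genes["chrom"].to_numpy(), n_probes),
            "start": starts,
            "end": starts + PROBE_LENGTH,
            "promoter_id": np.repeat(genes.index.to_numpy(), n_probes),
        }
    )

    # effect mask: 1 inside the promoter's DM sub-window
    win_start = genes["dm_win_start"].to_numpy()[:, None]
    win_len = genes["dm_win_len"].to_numpy()[:, None]
    in_window = (k[None, :] >= win_start) & (k[None, :] < win_start + win_len)
    dm_signal = (genes["dm_effect"].to_numpy()[:, None] * in_window).ravel()

    probe_affinity = rng.normal(0.0, 0.3, size=n_rows)
    a_baseline = rng.normal(10.0, 1.0, size=n_rows)
    families = sorted(design["family"].unique())
    # family effects act on the same local sub-window as the breed effect:
    # heritable methylation variation is confined to the regulatory element,
    # not smeared across the whole 10.5 kb tiling window
    window_mask = in_window.ravel()
    fam_eff = {
        f: np.repeat(rng.normal(0.0, cfg.family_effect_sd, size=len(genes)), n_probes)
        * window_mask
        for f in families
    }

    for _, s in design.iterrows():
        h = 1.0 if s["generation"] == "parent" else cfg.heritability
        mu = probe_affinity + h * (
            dm_signal * (s["breed"] == cfg.domestic) + fam_eff[s["family"]]
        )
        array_bias = rng.normal(0.0, 0.2)
        sd = cfg.noise_sd / np.sqrt(s["pool_size"])
        table[f"M_{s['sample_id']}"] = mu + array_bias + rng.normal(0.0, 1.0, size=n_rows) * sd
        table[f"A_{s['sample_id']}"] = (
            a_baseline + rng.normal(0.0, 0.3) + rng.normal(0.0, 0.1, size=n_rows)
        )
    return table


# ---------------------------------------------------------------------------
# melting curves


def melt_component(temps: np.ndarray, tm: float, width: float) -> np.ndarray:
    """Two-state melting sigmoid: fraction double-stranded, 1 -> 0."""
    return 1.0 / (1.0 + np.exp((np.asarray(temps, dtype=float) - tm) / width))


def generate_melt_curves(
    tm_unmeth: float,
    tm_meth: float,
    widths: float | tuple[float, float],
    fractions,
    temps=None,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    names=None,
) -> pd.DataFrame:
    """Mixture melting curves F(T) = f*S_meth(T) + (1-f)*S_unmeth(T) + noise.

    Methylated amplicons retain CG pairs after bisulfite conversion and melt
    at the higher temperature, so ``tm_meth`` must exceed ``tm_unmeth``.
    Default grid: 70-90 degC in 0.05 degC steps (401 points).  Returns a
    DataFrame with a ``temperature`` column and one fluorescence column per
    requested fraction.
    """
    if tm_meth <= tm_unmeth:
        raise ValueError("tm_meth must exceed tm_unmeth")
    if temps is None:
        temps = np.arange(0, 401) * 0.05 + 70.0
    temps = np.asarray(temps, dtype=float)
    if temps.size < 2 or np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    try:
        w_un, w_me = widths  # type: ignore[misc]
    except TypeError:
        w_un = w_me = float(widths)  # type: ignore[arg-type]
    s_un = melt_component(temps, tm_unmeth, w_un)
    s_me = melt_component(temps, tm_meth, w_me)
    if names is None:
        names = [f"f{int(round(100 * f)):03d}" for f in fractions]
    if rng is None:
        rng = np.random.default_rng(0)
    out = pd.DataFrame({"temperature": temps})
    for name, f in zip(names, fractions):
        curve = f * s_me + (1.0 - f) * s_un
        if noise > 0:
            curve = curve + rng.normal(0.0, noise, size=temps.size)
        out[name] = curve
    return out


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    design: pd.DataFrame
    truth: GroundTruth
    expression: pd.DataFrame
    probes: pd.DataFrame
    sweeps: pd.DataFrame
    covered: pd.DataFrame


def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Generate a complete dataset (design, truth, genome, expression,
    methylation) from one config."""
    design = generate_design(cfg)
    truth = make_ground_truth(cfg)
    sweeps = generate_sweeps(cfg, truth)
    expression = generate_expression(cfg, design, truth)
    probes = generate_methylation(cfg, design, truth)
    return SimulatedDataset(
        cfg=cfg,
        design=design,
        truth=truth,
        expression=expression,
        probes=probes,
        sweeps=sweeps,
        covered=truth.covered,
    )


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["genome"] = [list(x) for x in cfg.genome]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "genome" in d:
        d["genome"] = tuple((str(c), int(length)) for c, length in d["genome"])
    return SimConfig(**d)
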