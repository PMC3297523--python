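"""End-to-end orchestration: simulate -> normalize -> test -> summarise.

A single TOML config (plus one top-level seed) drives every stage; the seed
is split into named substreams per stage so reruns with the same config are
byte-identical and stages stay independent.  All tabular outputs are TSV
with a header; summaries are JSON; progress is logged to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import de_dm_stats, hrm_quant, sweep_enrichment, synthetic_data, tiling_norm, transgen_stability
from .synthetic_data import SimConfig, substream

logger = logging.getLogger("epiherit")

HRM_DEFAULTS = {
    "tm_unmeth": 78.0,
    "tm_meth": 82.0,
    "width": 0.5,
    "noise": 0.01,
    "n_per_group": 8,
    "frac_wild": 0.25,
    "frac_domestic": 0.70,
    "fraction_sd": 0.05,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def record(self, name: str, inputs: list[str], outputs: list[str], status: str) -> None:
        self.stages.append(
            {"stage": name, "inputs": inputs, "outputs": outputs, "status": status}
        )


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _fit_to_frame(fit: de_dm_stats.ModeratedTestFit) -> pd.DataFrame:
    out = fit.table.copy()
    out.insert(0, "feature", out.index)
    return out


def breed_fit(
    matrix: pd.DataFrame, design: pd.DataFrame, generation: str, wild: str, domestic: str
) -> de_dm_stats.ModeratedTestFit:
    """Breed contrast within one generation; positive log2FC = higher in the
    domesticated breed."""
    meta = design.set_index("sample_id")
    cols = [c for c in matrix.columns if meta.loc[c, "generation"] == generation]
    labels = meta.loc[cols, "breed"]
    return de_dm_stats.fit_moderated_t(matrix[cols], labels, groups=(wild, domestic))


def simulate_melt_curves(seed: int, hrm_cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibration series plus per-breed sample curves for the HRM stage.

    Emulates assaying one amplicon hypermethylated in the domestic breed:
    per-bird methylated fractions are drawn around breed-specific means.
    Returns (curves wide table, roles table).
    """
    cfg = {**HRM_DEFAULTS, **hrm_cfg}
    rng = substream(seed, "melt")
    cal_fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
    names = [f"cal{int(100 * f):03d}" for f in cal_fracs]
    roles = [
        {"sample_id": n, "role": "calibration", "group": "", "known_fraction": f * 100}
        for n, f in zip(names, cal_fracs)
    ]
    fracs = list(cal_fracs)
    n = int(cfg["n_per_group"])
    for group, mean_f in (("RJF", cfg["frac_wild"]), ("WL", cfg["frac_domestic"])):
        draws = np.clip(rng.normal(mean_f, cfg["fraction_sd"], size=n), 0.0, 1.0)
        for i, f in enumerate(draws):
            names.append(f"{group}_{i + 1:02d}")
            fracs.append(float(f))
            roles.append(
                {"sample_id": names[-1], "role": "sample", "group": group,
                 "known_fraction": float(f) * 100}
            )
    curves = synthetic_data.generate_melt_curves(
        cfg["tm_unmeth"], cfg["tm_meth"], cfg["width"], fracs,
        noise=cfg["noise"], rng=rng, names=names,
    )
    return curves, pd.DataFrame(roles)


def analyze_melt_curves(curves: pd.DataFrame, roles: pd.DataFrame) -> dict:
    """Normalize curves, locate T_md from the 0%/100% calibration controls,
    test the two breeds at T_md, and interpolate percent methylation."""
    temps = curves["temperature"].to_numpy()
    sample_cols = [c for c in curves.columns if c != "temperature"]
    norm = pd.DataFrame(
        {c: hrm_quant.normalize_curve(temps, curves[c].to_numpy()) for c in sample_cols}
    )
    t_md, degen = hrm_quant.find_tmd(temps, norm["cal100"], norm["cal000"])
    roles = roles.set_index("sample_id")
    groups = roles.loc[roles["role"] == "sample", "group"]
    res = hrm_quant.group_difference(temps, norm[list(groups.index)], groups, t_md, degen)

    cal = roles[roles["role"] == "calibration"]
    cal_int = [hrm_quant.intensity_at(temps, norm[s].to_numpy(), t_md) for s in cal.index]
    fractions = {}
    for s in groups.index:
        pct, _ = hrm_quant.estimate_fraction(
            res.intensities[s], cal["known_fraction"].to_numpy(), cal_int
        )
        fractions[s] = pct
    return {
        "t_md": res.t_md,
        "group_means": res.group_means,
        "welch_t": res.t,
        "welch_df": res.df,
        "p": res.p,
        "estimated_percent": fractions,
    }


def run_pipeline(config_path, outdir) -> RunManifest:
    """Execute every stage in dependency order and write a summary.

    Rerunning with the same config and seed reproduces every output
    byte-for-byte.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = config_path.read_bytes()
    config = tomllib.loads(raw.decode())
    seed = int(config.get("seed", 0))
    try:
        ver = pkg_version("epiherit")
    except Exception:
        ver = "unknown"
    manifest = RunManifest(
        config_hash=hashlib.sha256(raw).hexdigest(), seed=seed, version=ver
    )
    summary: dict = {"seed": seed}

    def stage(name):
        logger.info("stage %s ...", name)
        return time.time()

    def done(name, t0, inputs, outputs):
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
        manifest.record(name, inputs, [str(o) for o in outputs], "ok")

    # -- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    sim_cfg = SimConfig(seed=seed, **config.get("simulate", {}))
    ds = synthetic_data.simulate(sim_cfg)
    files = {
        "design": outdir / "design.tsv",
        "expression": outdir / "expression.tsv",
        "probes": outdir / "probes.tsv",
        "truth": outdir / "truth_genes.tsv",
    }
    _write_tsv(ds.design, files["design"])
    _write_tsv(ds.expression.rename_axis("gene_id").reset_index(), files["expression"])
    _write_tsv(ds.probes, files["probes"])
    _write_tsv(ds.truth.genes.reset_index(), files["truth"])
    genes_bed = ds.truth.genes.reset_index().rename(columns={"gene_id": "name"})
    sweep_enrichment.write_bed(genes_bed[["chrom", "start", "end", "name"]], outdir / "genes.bed")
    sweep_enrichment.write_bed(ds.sweeps, outdir / "sweeps.bed")
    sweep_enrichment.write_bed(ds.covered, outdir / "covered.bed")
    curves, roles = simulate_melt_curves(seed, config.get("hrm", {}))
    _write_tsv(curves, outdir / "melt_curves.tsv")
    _write_tsv(roles, outdir / "melt_roles.tsv")
    done("simulate", t0, [str(config_path)], list(files.values()))

    # -- normalize ---------------------------------------------------------
    t0 = stage("normalize")
    probes_norm = tiling_norm.normalize(ds.probes)
    _write_tsv(probes_norm, outdir / "probes_norm.tsv")
    done("normalize", t0, [str(files["probes"])], [outdir / "probes_norm.tsv"])

    # -- dedm --------------------------------------------------------------
    t0 = stage("dedm")
    fdr = float(config.get("dedm", {}).get("fdr", de_dm_stats.FDR_DEFAULT))
    wild, domestic = sim_cfg.breeds[0], sim_cfg.domestic
    expr_fit = {
        gen: breed_fit(ds.expression, ds.design, gen, wild, domestic)
        for gen in ("parent", "offspring")
    }
    m_cols = tiling_norm.m_columns(probes_norm)
    m_matrix = probes_norm[m_cols].copy()
    m_matrix.columns = [c[2:] for c in m_cols]
    m_matrix.index = probes_norm["probe_id"]
    meth_fit = {
        gen: breed_fit(m_matrix, ds.design, gen, wild, domestic)
        for gen in ("parent", "offspring")
    }
    promoter_calls = {
        gen: de_dm_stats.aggregate_promoters(meth_fit[gen], probes_norm, fdr=fdr)
        for gen in ("parent", "offspring")
    }
    de_calls = {gen: de_dm_stats.call_significant(expr_fit[gen], fdr) for gen in expr_fit}
    outs = []
    for gen in ("parent", "offspring"):
        for label, frame in (
            (f"expr_{gen}", _fit_to_frame(expr_fit[gen])),
            (f"meth_probes_{gen}", _fit_to_frame(meth_fit[gen])),
            (f"promoter_calls_{gen}", promoter_calls[gen].reset_index()),
        ):
            path = outdir / f"{label}.tsv"
            _write_tsv(frame, path)
            outs.append(path)
    summary["n_de"] = {gen: len(de_calls[gen]) for gen in de_calls}
    summary["n_dm"] = {
        gen: int(promoter_calls[gen]["significant"].sum()) for gen in promoter_calls
    }
    done("dedm", t0, [str(files["expression"])], outs)

    # -- stability ---------------------------------------------------------
    t0 = stage("stability")
    stab_cfg = config.get("stability", {})
    k = int(stab_cfg.get("top_k", 1000))
    conc_expr = transgen_stability.topk_concordance(expr_fit["parent"], expr_fit["offspring"], k)
    conc_meth = transgen_stability.topk_concordance(
        SimpleNamespace(table=promoter_calls["parent"]),
        SimpleNamespace(table=promoter_calls["offspring"]),
        k,
    )
    meta = ds.design.set_index("sample_id")
    pcols = [c for c in ds.expression.columns if meta.loc[c, "generation"] == "parent"]
    ocols = [c for c in ds.expression.columns if meta.loc[c, "generation"] == "offspring"]
    fam = transgen_stability.family_correlation_test(
        ds.expression[pcols], ds.expression[ocols], ds.design,
        between_scope=stab_cfg.get("between_scope", "breed"),
    )
    ov_frac, ov_n, ov_a = transgen_stability.overlap_fraction(
        de_calls["parent"], de_calls["offspring"]
    )
    try:
        bias = transgen_stability.bias_from_calls(
            promoter_calls["parent"], promoter_calls["offspring"]
        )
        bias_d = {
            "n_hyper": bias.n_hyper, "n_hypo": bias.n_hypo,
            "fraction_hyper": bias.fraction_hyper, "chi2": bias.chi2, "p": bias.p,
        }
    except ValueError:
        bias_d = None
    summary["stability"] = {
        "concordance_r_expression": conc_expr.r,
        "concordance_n_expression": conc_expr.n_selected,
        "concordance_r_methylation": conc_meth.r,
        "concordance_n_methylation": conc_meth.n_selected,
        "family_mean_difference": fam.mean_difference,
        "family_sem": fam.sem,
        "family_t": fam.t,
        "family_p": fam.p,
        "de_overlap_fraction": ov_frac,
        "de_overlap_n": ov_n,
        "de_parent_n": ov_a,
        "hyper_bias": bias_d,
    }
    stab_frame = pd.DataFrame(
        [{"metric": m, "value": v} for m, v in summary["stability"].items()
         if not isinstance(v, dict)]
    )
    _write_tsv(stab_frame, outdir / "stability.tsv")
    done("stability", t0, [], [outdir / "stability.tsv"])

    # -- sweeptest ---------------------------------------------------------
    t0 = stage("sweeptest")
    sw_cfg = config.get("sweeptest", {})
    de_both = sorted(set(de_calls["parent"]) & set(de_calls["offspring"]))
    query = ds.truth.genes.loc[de_both, ["chrom", "start", "end"]].reset_index()
    query = query.rename(columns={"gene_id": "name"})[["chrom", "start", "end", "name"]]
    if len(query):
        perm = sweep_enrichment.enrichment_test(
            query, ds.sweeps, ds.covered,
            window=int(sw_cfg.get("window", sweep_enrichment.PROXIMITY_WINDOW)),
            n_sets=int(sw_cfg.get("n_sets", sweep_enrichment.N_SETS_DEFAULT)),
            seed=substream(seed, "genome").integers(0, 2**31),
        )
        summary["sweep_enrichment"] = {
            "n_query": perm.n_query, "observed": perm.observed, "p": perm.p,
            "null_mean": float(perm.null_counts.mean()), "n_sets": perm.n_sets,
        }
    else:
        summary["sweep_enrichment"] = None
    done("sweeptest", t0, [], [])

    # -- hrm ---------------------------------------------------------------
    t0 = stage("hrm")
    summary["hrm"] = analyze_melt_curves(curves, roles)
    done("hrm", t0, [], [])

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "config_hash": manifest.config_hash,
                "seed": manifest.seed,
                "version": manifest.version,
                "stages": manifest.stages,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    logger.info("summary written to %s", summary_path)
    return manifest


def setup_logging(level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.setLevel(level)
    if not logger.handlers:
        logger.addHandler(handler)
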