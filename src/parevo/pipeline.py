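"""Stage orchestration: simulate-or-load, substitutions, GC*, diversity,
recombination, population parameters, gBGC, hominin phylogeny, report.

Each stage is a pure function of (config, seed, upstream outputs); it writes
its outputs plus a manifest recording inputs, parameters, the seed and
output checksums, so a rerun with the same config reproduces identical
files and downstream stages can be regenerated after deleting
intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import diversity as dv
from . import gbgc
from . import gc_equilibrium as gce
from . import io as pio
from . import phylo
from . import popgen
from . import recombination as rc
from . import synthetic as syn
from .datasets import constants

log = logging.getLogger("parevo")

STAGES = ("simulate", "subst", "gcstar", "diversity", "recomb", "params",
          "gbgc", "phylo", "report")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple = STAGES
    simulate: dict = field(default_factory=dict)
    gbgc_bootstrap: int = 20
    gcstar_bootstrap: int = 0
    phylo_length: int = 100_000
    phylo_bootstrap: int = 100
    constants: dict = field(default_factory=dict)

    def __post_init__(self):
        order = {s: i for i, s in enumerate(STAGES)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        self.stages = tuple(sorted(self.stages, key=order.__getitem__))
        merged = dict(constants())
        merged.update(self.constants)
        if any(isinstance(v, (int, float)) and v <= 0
               for k, v in merged.items() if k != "min_callable_sites"
               and not isinstance(v, (dict, list))):
            raise ValueError("constants must be positive")
        self.constants = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict,
                    inputs: list[str]) -> None:
    outputs = {p.name: _sha256(p) for p in sorted(stage_dir.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    manifest = {"stage": stage, "parameters": params, "inputs": inputs,
                "outputs": outputs}
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing dependency output {path}")
    return path


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns a report
    of per-stage output paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, dict] = {}
    for stage in config.stages:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        log.info("stage %s -> %s", stage, stage_dir)
        try:
            params = _RUNNERS[stage](config, out, stage_dir)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - label the failing stage
            raise StageError(stage, str(e)) from e
        _write_manifest(stage_dir, stage, params, inputs=[])
        report[stage] = {"dir": str(stage_dir)}
    return report


# ---------------------------------------------------------------- stages


def _stage_simulate(config: RunConfig, out: Path, d: Path) -> dict:
    cfg = syn.SimulationConfig(seed=config.seed, **config.simulate)
    aln, events = syn.simulate_alignment(cfg)
    al.write_fasta_alignment(d / "alignment.fa", aln)
    sites, ref = syn.simulate_polymorphism(cfg)
    dv.write_vcf(d / "population.vcf", sites)
    dv.write_sites_tsv(d / "sites.tsv", sites)
    with open(d / "reference.fa", "w") as fh:
        fh.write(">PAR1_sim\n" + "".join(ref) + "\n")
    pd.DataFrame({"sample": sites.samples, "sex": sites.sex}).to_csv(
        d / "samples.tsv", sep="\t", index=False, header=False)
    depth = syn.simulate_depth(cfg)
    pio.write_bedgraph(d / "depth.bedgraph", sites.chrom, depth)
    for i, pop in enumerate(("popA", "popB")):
        rmap = syn.simulate_recomb_map(cfg, population=pop,
                                       seed=cfg.seed + 10 + i)
        pio.write_tsv(d / f"recomb_{pop}.tsv", rmap.to_frame(sites.chrom))
    # a small exclusion mask to exercise neutral-site filtering
    rng = np.random.default_rng(cfg.seed + 5)
    starts = np.sort(rng.choice(cfg.length, size=5, replace=False))
    iv = pio.GenomicIntervals("PAR1_sim", starts, starts + cfg.length // 100)
    pio.write_bed(d / "mask_repeats.bed", iv)
    return {"seed": cfg.seed, "length": cfg.length,
            "region_length": cfg.region_length, "n_diploid": cfg.n_diploid}


def _subst_inputs(config: RunConfig, out: Path, stage: str):
    sim = out / "simulate"
    aln = al.read_fasta_alignment(_require(sim / "alignment.fa", stage),
                                  ref_name="PAR1_sim")
    masks = [pio.read_bed(sim / "mask_repeats.bed")]
    cfg = syn.SimulationConfig(seed=config.seed, **config.simulate)
    return al.filter_neutral_sites(aln, masks), cfg.tree()


def _stage_subst(config: RunConfig, out: Path, d: Path) -> dict:
    aln, tree = _subst_inputs(config, out, "subst")
    tallies, spectra = [], []
    for child, _ in tree.branches():
        if child == "M":
            continue  # outgroup branch: rooting only
        t = al.count_branch_substitutions(aln, tree, child)
        tallies.append(t)
        s = al.substitution_spectrum(t)
        s["branch"] = child
        spectra.append(s)
    pio.write_tsv(d / "tallies.tsv", al.tallies_to_frame(tallies))
    pio.write_tsv(d / "spectra.tsv", pd.DataFrame(spectra))
    return {"n_columns": aln.n_columns}


def _stage_gcstar(config: RunConfig, out: Path, d: Path) -> dict:
    aln, tree = _subst_inputs(config, out, "gcstar")
    rows = []
    for child, _ in tree.branches():
        if child == "M":
            continue
        rows.append(gce.gc_summary(aln, tree, child,
                                   chrom_length=aln.n_columns).to_series())
    pio.write_tsv(d / "gc_summary.tsv", pd.DataFrame(rows))
    if config.gcstar_bootstrap:
        boot = gce.bootstrap_gc_summary(aln, tree, "H",
                                        n_reps=config.gcstar_bootstrap,
                                        seed=config.seed)
        pio.write_tsv(d / "gc_bootstrap.tsv", boot)
    return {"bootstrap": config.gcstar_bootstrap}


def _stage_diversity(config: RunConfig, out: Path, d: Path) -> dict:
    sim = out / "simulate"
    sites = dv.read_sites_tsv(_require(sim / "sites.tsv", "diversity"))
    cfg = syn.SimulationConfig(seed=config.seed, **config.simulate)
    depth = pio.read_depth(_require(sim / "depth.bedgraph", "diversity"),
                           length=cfg.region_length)
    mask = dv.callable_mask_from_depth(depth, n=2 * cfg.n_diploid,
                                       mean_cov=cfg.mean_coverage,
                                       chrom=sites.chrom,
                                       window=config.constants["window_bp"])
    win = dv.window_statistics(sites, mask,
                               window=config.constants["window_bp"],
                               min_callable=config.constants["min_callable_sites"])
    pio.write_tsv(d / "window_stats.tsv", win)
    pio.write_tsv(d / "diversity_spectrum.tsv",
                  dv.diversity_spectrum(sites).rename("proportion").to_frame()
                  .reset_index(names="mut_class"))
    pio.write_tsv(d / "sex_scan.tsv", dv.sex_diff_scan(sites))
    return {"windows": len(win)}


def _stage_recomb(config: RunConfig, out: Path, d: Path) -> dict:
    sim = out / "simulate"
    maps = []
    for pop in ("popA", "popB"):
        df = pio.read_recomb_map(_require(sim / f"recomb_{pop}.tsv", "recomb"))
        maps.append(rc.RecombMap.from_frame(df, population=pop))
    target = config.constants["target_mean_cmmb"]
    low, high = config.constants["recomb_bin_cuts_cmmb"]
    scaled = [rc.scale_to_cmmb(m, target) for m in maps]
    mean_map = rc.genus_mean_map(scaled, population="genus_mean")
    pio.write_tsv(d / "mean_map.tsv", mean_map.to_frame())
    bins = rc.assign_bins(mean_map, low, high)
    with open(d / "bins.bed", "w") as fh:
        for s, b in zip(mean_map.starts, bins):
            fh.write(f"PAR1_sim\t{s}\t{s + mean_map.window}\t{b}\n")
    rho, p = rc.window_correlation(scaled[0].rates, scaled[1].rates,
                                   scaled[0].usable, scaled[1].usable)
    pio.write_tsv(d / "correlation.tsv",
                  pd.DataFrame([{"a": "popA", "b": "popB",
                                 "spearman": rho, "p": p}]))
    return {"target_mean": target, "cuts": [low, high]}


def _stage_params(config: RunConfig, out: Path, d: Path) -> dict:
    table = popgen.population_params_table(
        genetic_length=config.constants["par1_genetic_length_morgans"])
    pio.write_tsv(d / "population_params.tsv", table)
    return {"populations": len(table)}


def _stage_gbgc(config: RunConfig, out: Path, d: Path) -> dict:
    sim = out / "simulate"
    sites = dv.read_sites_tsv(_require(sim / "sites.tsv", "gbgc"))
    gc_changing = (np.isin(sites.ref, ("C", "G"))
                   != np.isin(sites.alt, ("C", "G")))
    log.info("gbgc: %d GC-conservative sites set aside", int((~gc_changing).sum()))
    sites = sites.subset(gc_changing)
    results = []
    for selector in gbgc.CLASS_SELECTORS:
        afs = gbgc.build_gc_afs(sites, selector)
        if afs.total < 50:
            continue
        fit = gbgc.bootstrap_B(gbgc.trim_extremes(afs),
                               n_reps=config.gbgc_bootstrap, seed=config.seed)
        results.append({"class": selector, "B": fit.B,
                        "theta_ws": fit.theta_ws, "theta_sw": fit.theta_sw,
                        "loglik": fit.loglik, "ci_low": fit.ci[0],
                        "ci_high": fit.ci[1], "n_sites": afs.total})
        pd.DataFrame({"B": fit.replicates}).to_csv(
            d / f"bootstrap_{selector}.tsv", sep="\t", index=False)
    pio.write_tsv(d / "gbgc_fits.tsv", pd.DataFrame(results))
    return {"bootstrap": config.gbgc_bootstrap}


def _stage_phylo(config: RunConfig, out: Path, d: Path) -> dict:
    aln = syn.simulate_hominin_alignment(length=config.phylo_length,
                                         seed=config.seed)
    seqs = {l: aln.seqs[l] for l in ("H", "N", "D", "C")}
    dm = phylo.distance_matrix(seqs)
    tree = phylo.nj_tree(dm)
    with open(d / "nj_tree.nwk", "w") as fh:
        fh.write(tree.to_newick(root_on="C") + "\n")
    support = phylo.bootstrap_support(seqs, n_reps=config.phylo_bootstrap,
                                      seed=config.seed)
    rows = [{"bipartition": "|".join(sorted(bp)), "support": v}
            for bp, v in support.items()]
    pio.write_tsv(d / "bootstrap_support.tsv", pd.DataFrame(rows))
    pio.write_tsv(d / "distances.tsv",
                  pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels)
                  .reset_index(names="taxon"))
    return {"taxa": list(seqs)}


def _stage_report(config: RunConfig, out: Path, d: Path) -> dict:
    """Join stage outputs into divergence-, population- and bin-style tables
    (no statistic is recomputed here)."""
    tal = pd.read_csv(_require(out / "subst" / "tallies.tsv", "report"), sep="\t")
    total = tal[list(al.CLASSES)].sum(axis=1)
    t1 = pd.DataFrame({"branch": tal["branch"],
                       "total_divergence": total / tal["n_scored"]})
    ages = syn.SimulationConfig(seed=config.seed, **config.simulate).tree().lengths
    pio.write_tsv(d / "table_divergence.tsv", t1)

    params = pd.read_csv(_require(out / "params" / "population_params.tsv",
                                  "report"), sep="\t")
    fits = pd.read_csv(_require(out / "gbgc" / "gbgc_fits.tsv", "report"),
                       sep="\t")
    pooled_b = fits.loc[fits["class"] == "pooled", "B"]
    params["B_sim"] = float(pooled_b.iloc[0]) if len(pooled_b) else np.nan
    pio.write_tsv(d / "table_populations.tsv", params)

    win = pd.read_csv(_require(out / "diversity" / "window_stats.tsv",
                               "report"), sep="\t")
    bins = pd.read_csv(_require(out / "recomb" / "bins.bed", "report"),
                       sep="\t", names=["chrom", "start", "end", "bin"])
    joined = win.merge(bins[["start", "bin"]], on="start", how="left")
    by_bin = (joined[joined["pass_filter"]]
              .groupby("bin")[["pi", "theta_w", "tajimas_d"]].mean()
              .reset_index())
    pio.write_tsv(d / "table_by_bin.tsv", by_bin)
    with open(d / "footnotes.json", "w") as fh:
        json.dump(config.constants, fh, indent=1, sort_keys=True)
    return {"tables": ["table_divergence.tsv", "table_populations.tsv",
                       "table_by_bin.tsv"]}


_RUNNERS = {"simulate": _stage_simulate, "subst": _stage_subst,
            "gcstar": _stage_gcstar, "diversity": _stage_diversity,
            "recomb": _stage_recomb, "params": _stage_params,
            "gbgc": _stage_gbgc, "phylo": _stage_phylo,
            "report": _stage_report}
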