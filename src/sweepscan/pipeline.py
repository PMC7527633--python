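"""End-to-end pipeline: simulate → filter → annotate → stats → scan → structure.

Stage outputs are plain TSV/BED/JSON so every stage is independently
diffable; a run manifest records the configuration, per-stage outputs
with checksums, and wall times.  Re-running with the same configuration
and inputs reproduces byte-identical statistic tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import pop_structure, popgen_stats, sweep_scan, synthetic_data, variants_io
from .genotypes import GenotypeMatrix
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


DEFAULT_PARAMS = {
    "window_size": 100_000,
    "step_size": 10_000,
    "min_snvs": 10,
    "q": 0.01,
    "estimator": "wc",
    "scan_filter": {"min_call_rate": 0.90, "min_maf": 0.05,
                    "max_missing": 0.20},
    "structure_filter": {"min_maf": 0.05, "max_missing": 0.05,
                         "min_qual": 30},
    "prune": {"window_snps": 100, "step_snps": 10, "r2_max": 0.2},
    "ld_decay": {"max_dist": 300_000, "bin_width": 500, "max_sites": 20_000},
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` (simulate a cohort first) or ``vcf``
    (+ ``populations``) must be provided.  ``params`` carries all window
    and threshold settings; missing keys take the defaults above.
    """

    outdir: Path
    simulation: SimulationConfig | None = None
    vcf: Path | None = None
    populations: Path | None = None
    gff3: Path | None = None
    fasta: Path | None = None
    features: Path | None = None
    truth: Path | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        merged = json.loads(json.dumps(DEFAULT_PARAMS))
        for key, val in (self.params or {}).items():
            if isinstance(val, dict) and key in merged:
                merged[key].update(val)
            else:
                merged[key] = val
        self.params = merged

    def validate(self) -> None:
        if (self.simulation is None) == (self.vcf is None):
            raise ConfigError(
                "provide exactly one of a simulation block or a VCF input")
        if self.vcf is not None and self.populations is None:
            raise ConfigError("VCF input requires a sample->population map")
        p = self.params
        if not (0 < p["q"] < 0.5):
            raise ConfigError("q must lie in (0, 0.5)")
        if p["estimator"] not in ("wc", "hudson"):
            raise ConfigError("estimator must be 'wc' or 'hudson'")
        if p["step_size"] > p["window_size"]:
            raise ConfigError("step_size must not exceed window_size")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: Path | str, outdir: Path | str | None = None,
                  seed: int | None = None) -> "RunConfig":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, outdir=outdir, seed=seed)

    @classmethod
    def from_dict(cls, doc: dict, outdir: Path | str | None = None,
                  seed: int | None = None) -> "RunConfig":
        sim = doc.get("simulation")
        inp = doc.get("input", {})
        cfg = cls(
            outdir=Path(outdir if outdir is not None
                        else doc.get("outdir", "sweepscan_run")),
            simulation=(SimulationConfig.from_dict(sim)
                        if sim is not None else None),
            vcf=Path(inp["vcf"]) if "vcf" in inp else None,
            populations=(Path(inp["populations"])
                         if "populations" in inp else None),
            gff3=Path(inp["gff3"]) if "gff3" in inp else None,
            fasta=Path(inp["fasta"]) if "fasta" in inp else None,
            features=Path(inp["features"]) if "features" in inp else None,
            truth=Path(inp["truth"]) if "truth" in inp else None,
            params=doc.get("params", {}),
            seed=doc.get("seed", 0),
        )
        if seed is not None:
            cfg.seed = seed
            if cfg.simulation is not None:
                cfg.simulation.seed = seed
        return cfg

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "simulation": (self.simulation.to_dict()
                           if self.simulation else None),
            "input": {k: str(v) for k, v in {
                "vcf": self.vcf, "populations": self.populations,
                "gff3": self.gff3, "fasta": self.fasta,
                "features": self.features, "truth": self.truth,
            }.items() if v is not None},
            "params": self.params,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sweepscan",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("filter", _stage_filter),
        ("annotate", _stage_annotate),
        ("stats", _stage_stats),
        ("scan", _stage_scan),
        ("structure", _stage_structure),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(config, state, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            _write_json(manifest, outdir / "manifest.json")
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "checksums": {k: _sha256(Path(v)) for k, v in outputs.items()},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    if config.simulation is None:
        # VCF mode: record the provided inputs and move on
        state["vcf"] = config.vcf
        state["populations"] = variants_io.read_populations_tsv(
            config.populations)
        state["gff3"] = config.gff3
        state["fasta"] = config.fasta
        state["features"] = config.features
        state["truth_intervals"] = (
            [tuple(r) for r in sweep_scan.read_bed(config.truth)
             [["chrom", "start", "end"]].itertuples(index=False)]
            if config.truth else None)
        state["chrom_lengths"] = None
        return {}
    sim_cfg = config.simulation
    genotypes, truth = synthetic_data.simulate_cohort(sim_cfg)
    paths = synthetic_data.write_cohort(genotypes, truth, outdir / "sim")
    state["vcf"] = paths["vcf"]
    state["populations"] = {
        sid: pop for sid, pop in zip(genotypes.sample_ids,
                                     genotypes.populations)}
    state["gff3"] = paths["gff3"]
    state["fasta"] = paths["fasta"]
    state["features"] = paths["truth_bed"]
    state["truth_intervals"] = truth.sweep_intervals
    state["chrom_lengths"] = dict(sim_cfg.chrom_lengths)
    return paths


def _stage_filter(config: RunConfig, state: dict, outdir: Path) -> dict:
    g, read_stats = variants_io.read_vcf(
        state["vcf"], state["populations"], with_stats=True)
    state["raw"] = g
    scan_g, removed = variants_io.filter_sites_scan(
        g, **config.params["scan_filter"])
    state["scan_matrix"] = scan_g
    summary = {
        "n_records": read_stats["n_records"],
        "skipped_multiallelic": read_stats["skipped_multiallelic"],
        "skipped_non_snv": read_stats["skipped_non_snv"],
        "n_snvs_raw": g.n_sites,
        "tstv_raw": variants_io.tstv_ratio(g),
        "scan_filter_removed": removed,
        "n_snvs_scan": scan_g.n_sites,
    }
    state["filter_summary"] = summary
    path = outdir / "filter_summary.json"
    _write_json(summary, path)
    filtered_vcf = outdir / "filtered.vcf"
    synthetic_data.write_vcf(scan_g, filtered_vcf, state["chrom_lengths"])
    return {"filter_summary": path, "filtered_vcf": filtered_vcf}


def _stage_annotate(config: RunConfig, state: dict, outdir: Path) -> dict:
    if state.get("gff3") is None:
        logger.info("no gene models provided; annotation skipped")
        state["genes"] = None
        state["annotation_summary"] = None
        return {}
    genes = variants_io.read_gff3(state["gff3"])
    state["genes"] = genes
    ann = variants_io.annotate_variants(
        state["raw"], genes, reference=state.get("fasta"))
    summary = variants_io.annotation_summary(ann)
    state["annotation_summary"] = summary
    ann_path = outdir / "annotation.tsv"
    sum_path = outdir / "annotation_summary.tsv"
    _write_tsv(ann, ann_path)
    _write_tsv(summary, sum_path)
    return {"annotation": ann_path, "annotation_summary": sum_path}


def _stage_stats(config: RunConfig, state: dict, outdir: Path) -> dict:
    g = state["scan_matrix"]
    chrom_lengths = state["chrom_lengths"]
    if chrom_lengths is None:
        # infer from the data: last position per chromosome
        chrom_lengths = {
            str(c): int(p) for c, p in
            g.sites.groupby("chrom")["pos"].max().items()}
    grid = popgen_stats.make_windows(
        chrom_lengths, config.params["window_size"], config.params["step_size"])
    stats = popgen_stats.window_statistics(
        g, grid, estimator=config.params["estimator"],
        min_snvs=config.params["min_snvs"])
    state["window_stats"] = stats
    path = outdir / "windows.tsv"
    _write_tsv(stats, path)
    return {"windows": path}


def _stage_scan(config: RunConfig, state: dict, outdir: Path) -> dict:
    stats = state["window_stats"]
    thresholds = sweep_scan.compute_thresholds(stats, config.params["q"])
    selected = sweep_scan.select_windows(stats, thresholds)
    regions = sweep_scan.merge_regions(selected)
    outputs: dict[str, Path] = {}

    if state.get("genes"):
        regions, gene_list = sweep_scan.genes_in_regions(
            regions, state["genes"])
    else:
        gene_list = []
    state["regions"] = regions

    bed_path = outdir / "regions.bed"
    with bed_path.open("w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\tsweep\n")
    outputs["regions_bed"] = bed_path
    tsv_path = outdir / "regions.tsv"
    _write_tsv(regions, tsv_path)
    outputs["regions_tsv"] = tsv_path

    summary = sweep_scan.scan_summary(stats, selected, regions, thresholds)
    summary["n_genes_in_regions"] = len(gene_list)
    summary["genes"] = gene_list
    if state.get("features") is not None:
        feats = sweep_scan.read_bed(state["features"])
        overlap = sweep_scan.feature_overlap(regions, feats)
        feat_path = outdir / "feature_overlap.tsv"
        _write_tsv(overlap, feat_path)
        outputs["feature_overlap"] = feat_path
    if state.get("truth_intervals"):
        summary["recovery"] = sweep_scan.score_recovery(
            regions, state["truth_intervals"])
    state["scan_summary"] = summary
    sum_path = outdir / "scan_summary.json"
    _write_json(summary, sum_path)
    outputs["scan_summary"] = sum_path
    thr_path = outdir / "thresholds.json"
    _write_json({"fst_threshold": thresholds.fst_threshold,
                 "ratio_threshold": thresholds.ratio_threshold,
                 "q": thresholds.q}, thr_path)
    outputs["thresholds"] = thr_path
    return outputs


def _stage_structure(config: RunConfig, state: dict, outdir: Path) -> dict:
    g, removed = variants_io.filter_sites_structure(
        state["raw"], **config.params["structure_filter"])
    pruned = variants_io.ld_prune(g, **config.params["prune"])

    dist = pop_structure.ibs_distance(pruned)
    tree = pop_structure.neighbor_joining(dist)
    coords, var_exp = pop_structure.genotype_pca(pruned)

    ld_params = dict(config.params["ld_decay"])
    max_sites = ld_params.pop("max_sites", None)
    ld_g = g
    if max_sites and g.n_sites > max_sites:
        stride = int(np.ceil(g.n_sites / max_sites))
        ld_g = g.take_sites(np.arange(0, g.n_sites, stride))
    pops = ld_g.pop_labels()
    decay = []
    for pop in pops:
        curve = pop_structure.ld_decay(ld_g, pop, **ld_params)
        curve.insert(0, "population", pop)
        decay.append(curve)
    decay_df = pd.concat(decay, ignore_index=True)

    outputs = {}
    phylip_path = outdir / "ibs_distances.phylip"
    pop_structure.write_phylip(dist, phylip_path)
    outputs["distances"] = phylip_path
    tree_path = outdir / "nj_tree.nwk"
    tree_path.write_text(pop_structure.to_newick(tree) + "\n")
    outputs["tree"] = tree_path
    pca_path = outdir / "pca_coords.tsv"
    pca_df = pd.DataFrame(
        coords, columns=[f"PC{k+1}" for k in range(coords.shape[1])])
    pca_df.insert(0, "sample", pruned.sample_ids)
    pca_df.insert(1, "population", pruned.populations)
    _write_tsv(pca_df, pca_path)
    outputs["pca_coords"] = pca_path
    eig_path = outdir / "pca_variance.tsv"
    _write_tsv(pd.DataFrame({
        "component": np.arange(1, len(var_exp) + 1),
        "variance_explained": var_exp}), eig_path)
    outputs["pca_variance"] = eig_path
    ld_path = outdir / "ld_decay.tsv"
    _write_tsv(decay_df, ld_path)
    outputs["ld_decay"] = ld_path

    state["structure_summary"] = {
        "structure_filter_removed": removed,
        "n_snvs_structure": g.n_sites,
        "n_snvs_pruned": pruned.n_sites,
        "pc1_variance_pct": float(var_exp[0] * 100.0),
        "pc2_variance_pct": float(var_exp[1] * 100.0) if len(var_exp) > 1 else 0.0,
        "populations_monophyletic": pop_structure.is_monophyletic(
            tree, {sid for sid, pop in zip(pruned.sample_ids,
                                           pruned.populations)
                   if pop == pops[0]}),
    }
    sum_path = outdir / "structure_summary.json"
    _write_json(state["structure_summary"], sum_path)
    outputs["structure_summary"] = sum_path
    return outputs


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _load_json(path: Path):
    if path.exists():
        with path.open() as fh:
            return json.load(fh)
    return None


def report(run_dir: Path | str) -> str:
    """Assemble a human-readable summary of a completed run.

    Missing stage outputs are flagged rather than fatal; the report is
    written to ``report.md`` inside the run directory and returned.
    """
    run_dir = Path(run_dir)
    lines = ["# sweepscan run report", ""]
    filt = _load_json(run_dir / "filter_summary.json")
    if filt:
        lines += ["## Variants and filters", ""]
        lines.append(f"- VCF records read: {filt['n_records']}")
        lines.append(f"- biallelic SNVs retained: {filt['n_snvs_raw']} "
                     f"(skipped {filt['skipped_multiallelic']} multiallelic, "
                     f"{filt['skipped_non_snv']} non-SNV)")
        lines.append(f"- Ts/Tv: {filt['tstv_raw']:.3f}")
        rem = filt["scan_filter_removed"]
        lines.append(f"- scan filter removed {rem['total_removed']} sites "
                     f"(call rate {rem['call_rate']}, MAF {rem['maf']}, "
                     f"missingness {rem['missing']}); "
                     f"{filt['n_snvs_scan']} SNVs enter the scan")
        lines.append("")
    else:
        lines += ["## Variants and filters", "", "- MISSING", ""]

    ann_path = run_dir / "annotation_summary.tsv"
    lines += ["## Functional annotation", ""]
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        lines.append("| category | count | percent |")
        lines.append("|---|---:|---:|")
        for _, row in ann.iterrows():
            lines.append(f"| {row['category']} | {int(row['count'])} | "
                         f"{row['percent']:.2f} |")
        lines.append(f"| total | {int(ann['count'].sum())} | 100.00 |")
    else:
        lines.append("- no gene models provided")
    lines.append("")

    win_path = run_dir / "windows.tsv"
    lines += ["## Window statistics", ""]
    if win_path.exists():
        win = pd.read_csv(win_path, sep="\t")
        valid = win[win["valid"]]
        finite_ratio = valid["pi_ratio"].replace(
            [np.inf, -np.inf], np.nan).dropna()
        lines.append(f"- windows: {len(win)} ({len(valid)} valid)")
        lines.append(f"- mean SNVs per valid window: "
                     f"{valid['n_snvs'].mean():.1f}")
        for name, col in (("F_ST", valid["fst"]), ("pi-ratio", finite_ratio)):
            qs = col.quantile([0.5, 0.95, 0.99])
            lines.append(f"- {name} quantiles (50/95/99%): "
                         f"{qs.iloc[0]:.4f} / {qs.iloc[1]:.4f} / "
                         f"{qs.iloc[2]:.4f}")
    else:
        lines.append("- MISSING")
    lines.append("")

    scan = _load_json(run_dir / "scan_summary.json")
    lines += ["## Selection scan", ""]
    if scan:
        lines.append(f"- thresholds (top {100 * scan['q']:.0f}%): "
                     f"F_ST {scan['fst_threshold']:.6f}, "
                     f"pi-ratio {scan['ratio_threshold']:.6f}")
        lines.append(f"- selected windows: {scan['n_selected_windows']}")
        lines.append(f"- merged regions: {scan['n_regions']} covering "
                     f"{scan['total_region_bp'] / 1e6:.2f} Mb")
        lines.append(f"- mean SNVs per selected window: "
                     f"{scan['mean_snvs_per_selected_window']:.1f}")
        lines.append(f"- genes in regions: {scan['n_genes_in_regions']}")
        if "recovery" in scan:
            rec = scan["recovery"]
            lines.append(f"- recovery vs planted sweeps: precision "
                         f"{rec['precision']:.3f}, recall "
                         f"{rec['recall']:.3f}, interval recall "
                         f"{rec['interval_recall']:.3f}, Jaccard "
                         f"{rec['jaccard']:.3f}")
    else:
        lines.append("- MISSING")
    lines.append("")

    struct = _load_json(run_dir / "structure_summary.json")
    lines += ["## Population structure", ""]
    if struct:
        lines.append(f"- SNVs after structure filter: "
                     f"{struct['n_snvs_structure']} "
                     f"({struct['n_snvs_pruned']} after LD pruning)")
        lines.append(f"- PC1/PC2 variance explained: "
                     f"{struct['pc1_variance_pct']:.2f}% / "
                     f"{struct['pc2_variance_pct']:.2f}%")
        mono = struct["populations_monophyletic"]
        lines.append(f"- NJ tree separates the populations: "
                     f"{'yes' if mono else 'no'}")
    else:
        lines.append("- MISSING")
    lines.append("")

    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
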