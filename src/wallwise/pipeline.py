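"""End-to-end orchestration: simulate -> preprocess -> DE -> HVG -> GO
filter -> summaries, plus the chemistry branch.

Every stage writes its tables to the output directory so the pipeline can
be re-run from any intermediate point, and a manifest JSON records the
config hash, seed, package version and per-stage row counts.  A config
plus seed fully determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import filter_by_go, load_annotations, summarize_counts
from .chem_stats import ContrastOptions, contrast_table
from .config import RunConfig, _plain
from .containers import CountsExperiment
from .hvg import build_and_merge_lists
from .preprocess import filter_low_expressed, upper_quartile_normalize
from .simulate import simulate_chem_dataset, simulate_experiment, simulate_go_annotations
from .timecourse import run_contrasts

log = logging.getLogger(__name__)


def _config_hash(config: RunConfig) -> str:
    text = yaml.safe_dump(_plain(config.to_dict()), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, stages: dict, name: str) -> None:
    manifest = {
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "wallwise_version": __version__,
        "stages": stages,
    }
    (outdir / name).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_transcriptome_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full transcriptome branch into ``outdir``.

    Returns a dict with the in-memory objects of each stage (experiment,
    truth, annotations, normalized matrix, DE results, HVG collection,
    cell-wall tags and summary).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    stages: dict = {}

    log.info("stage simulate: %d genes", config.simulation.n_genes)
    experiment, truth = simulate_experiment(config.simulation)
    annotations = simulate_go_annotations(experiment.gene_ids, config.simulation, truth)
    experiment.write_tsv(outdir / "counts.tsv", outdir / "design.tsv")
    truth.write_tsv(outdir / "truth.tsv")
    annotations.write_tsv(outdir / "annotations.tsv")
    annotations.write_curated(outdir / "curated_genes.txt")
    annotations.write_families(outdir / "families.tsv")
    config.to_yaml(outdir / "config.yaml")
    stages["simulate"] = {"n_genes": int(len(experiment.gene_ids)),
                          "n_samples": int(len(experiment.sample_ids))}

    log.info("stage preprocess: filter + upper-quartile normalization")
    filtered = filter_low_expressed(experiment, min_mean=params.min_mean)
    norm = upper_quartile_normalize(filtered)
    norm.write_tsv(outdir / "normalized.tsv", outdir / "size_factors.tsv")
    stages["preprocess"] = {"n_genes_kept": int(len(filtered.gene_ids))}

    log.info("stage de: time-course contrasts")
    sim = config.simulation
    de_results = run_contrasts(norm, spline_df=params.spline_df,
                               drought_weeks=sim.drought_weeks,
                               recovery_weeks=sim.recovery_weeks)
    for (condition, window, genotype), res in de_results.items():
        res.write_tsv(outdir / f"de_{condition}_{window}_{genotype}.tsv")
    stages["de"] = {"n_contrasts": len(de_results)}

    log.info("stage hvg: combine, adjust, select, merge")
    collection = build_and_merge_lists(de_results, fraction=params.hvg_fraction,
                                       alpha=params.alpha, lfc_mode=params.lfc_mode)
    collection.write_tsv(outdir)
    stages["hvg"] = {"n_lists": len(collection.lists),
                     "n_merged": len(collection.merged)}

    log.info("stage gofilter: cell-wall restriction + summary")
    cw_tags = filter_by_go(collection.merged_genes, annotations)
    summary = summarize_counts(cw_tags, collection, annotations,
                               tissue=sim.tissue,
                               focus_weeks=params.focus_weeks,
                               trend_band=params.trend_band)
    pd.DataFrame({"gene_id": list(cw_tags),
                  "tags": [";".join(v) for v in cw_tags.values()]}
                 ).to_csv(outdir / "cw_genes.tsv", sep="\t", index=False)
    summary.write_tsv(outdir / "cw_summary.tsv", outdir / "cw_gene_report.tsv")
    stages["gofilter"] = {"n_cellwall_hvgs": len(cw_tags)}

    _write_manifest(outdir, config, stages, "manifest.json")
    return {"experiment": experiment, "truth": truth, "annotations": annotations,
            "normalized": norm, "de_results": de_results, "collection": collection,
            "cw_tags": cw_tags, "summary": summary}


def run_chem_pipeline(config: RunConfig, outdir) -> dict:
    """Run the chemistry branch: simulate assays, contrast vs control.

    Contrasts are reported for the configured focus weeks (7 and 14 by
    default, the pre- and post-flowering sampling points); a focus week
    absent from the assay design is reported as missing with a warning,
    not an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    stages: dict = {}

    table, truth = simulate_chem_dataset(config.chem)
    table.write_tsv(outdir / "analytes.tsv")
    truth.to_csv(outdir / "chem_truth.tsv", sep="\t", index=False)
    stages["chem_simulate"] = {"n_rows": int(len(table.data))}

    present = set(table.data["week"].unique())
    for wk in params.focus_weeks:
        if wk not in present:
            log.warning("focus week %s absent from assay design; report skipped", wk)
    focus = [wk for wk in params.focus_weeks if wk in present]
    sub = AnalyteSubset(table, focus)
    contrasts = contrast_table(sub.table, ContrastOptions(
        alpha=params.chem_alpha, fdr=params.fdr))
    contrasts.to_csv(outdir / "chem_contrasts.tsv", sep="\t", index=False)
    stages["chem_contrasts"] = {"n_contrasts": int(len(contrasts)),
                                "n_significant": int(contrasts["significant"].sum())
                                if len(contrasts) else 0}

    _write_manifest(outdir, config, stages, "chem_manifest.json")
    return {"analytes": table, "truth": truth, "contrasts": contrasts}


class AnalyteSubset:
    """Analyte table restricted to a set of weeks (keeps validation)."""

    def __init__(self, table, weeks):
        from .chem import AnalyteTable
        self.table = AnalyteTable(table.data[table.data["week"].isin(weeks)]
                                  .reset_index(drop=True))


def run_all(config: RunConfig, outdir) -> dict:
    """Both branches into one output directory."""
    out = run_transcriptome_pipeline(config, outdir)
    out.update(run_chem_pipeline(config, outdir))
    return out


# file-driven stage entry points for the CLI ------------------------------

def preprocess_files(counts_path, design_path, outdir, min_mean: float = 1.0) -> None:
    experiment = CountsExperiment.read_tsv(counts_path, design_path)
    filtered = filter_low_expressed(experiment, min_mean=min_mean)
    norm = upper_quartile_normalize(filtered)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    norm.write_tsv(outdir / "normalized.tsv", outdir / "size_factors.tsv")


def de_files(normalized_path, factors_path, design_path, outdir,
             spline_df: int = 4, drought_weeks=(3, 8), recovery_weeks=(9, 17)) -> None:
    from .containers import NormalizedMatrix
    norm = NormalizedMatrix.read_tsv(normalized_path, factors_path, design_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (condition, window, genotype), res in run_contrasts(
            norm, spline_df=spline_df, drought_weeks=drought_weeks,
            recovery_weeks=recovery_weeks).items():
        res.write_tsv(outdir / f"de_{condition}_{window}_{genotype}.tsv")


def hvg_files(de_dir, outdir, fraction: float = 0.05, alpha: float = 0.05,
              lfc_mode: str = "signed_mean") -> None:
    from .timecourse import DEResult
    de_dir = Path(de_dir)
    results = {}
    for path in sorted(de_dir.glob("de_*.tsv")):
        res = DEResult.read_tsv(path)
        results[(res.condition, res.window, res.genotype)] = res
    if not results:
        raise FileNotFoundError(f"no de_*.tsv tables under {de_dir}")
    collection = build_and_merge_lists(results, fraction=fraction, alpha=alpha,
                                       lfc_mode=lfc_mode)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection.write_tsv(outdir)


def gofilter_files(merged_path, annotations_path, outdir, curated_path=None) -> None:
    annotations = load_annotations(annotations_path, curated_path=curated_path)
    genes = [ln.strip() for ln in Path(merged_path).read_text().splitlines() if ln.strip()]
    tags = filter_by_go(genes, annotations)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene_id": list(tags), "tags": [";".join(v) for v in tags.values()]}
                 ).to_csv(outdir / "cw_genes.tsv", sep="\t", index=False)
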