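"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the field design being analyzed: two genotypes,
three irrigation conditions (watered control, pre-flowering drought with
watering withheld weeks 3-8 followed by recovery, post-flowering drought
with watering withheld weeks 10-17), 17 weekly time points and three
replicate plots, one tissue per run.  Counts are negative binomial around
genotype/condition/week means with per-sample library-size factors;
drought-responsive genes carry planted smooth log2 fold-change
trajectories relative to control.

Two response archetypes are planted.  A small *sustained* core responds
across the whole stress window (and, attenuated, through recovery for
the pre-flowering regime) - these emulate the cell-wall drought program
whose members the HVG selection should recover, and they are the pool
from which cell-wall GO annotations are preferentially drawn.  The
larger *transient* background responds in a short sub-window, which is
detectable by the time-course test but carries a small time-averaged
fold change, as most stress-responsive expression does.

Every planted trajectory is rescaled so its peak |log2 fold change|
equals ``effect_size_log2`` exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CELL_WALL_GO_TERMS, GOAnnotationSet
from .chem import AnalyteTable
from .config import ChemSimConfig, SimulationConfig
from .containers import CountsExperiment

log = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Deterministic rounding of expected set sizes (0.5 rounds up)."""
    return int(math.floor(x + 0.5))


@dataclass
class TruthTable:
    """Ground-truth labels behind a simulated experiment.

    ``table`` is indexed by gene id with boolean columns ``responsive``,
    ``sustained``, per-condition responsiveness flags, the trajectory
    sign, and (once annotations are simulated) ``cellwall``;
    ``trajectories`` maps each non-control condition to a genes x weeks
    matrix of planted log2 fold changes (all-zero rows for non-responsive
    genes).
    """

    table: pd.DataFrame
    trajectories: dict = field(default_factory=dict)

    @property
    def responsive_genes(self) -> pd.Index:
        return self.table.index[self.table["responsive"]]

    @property
    def cellwall_responsive_genes(self) -> pd.Index:
        return self.table.index[self.table["responsive"] & self.table["cellwall"]]

    def write_tsv(self, path, trajectories_dir=None) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")
        if trajectories_dir is not None:
            out = Path(trajectories_dir)
            for cond, traj in self.trajectories.items():
                traj.to_csv(out / f"truth_trajectory_{cond}.tsv", sep="\t",
                            index_label="gene_id")


def _window_shape(weeks: np.ndarray, lo: int, hi: int, flat: bool) -> np.ndarray:
    """Smooth bump over the inclusive week window [lo, hi], zero outside,
    peak exactly 1 at the assayed weeks.  ``flat=True`` flattens the top
    (sustained response), otherwise a half-sine (transient pulse)."""
    shape = np.zeros(weeks.size)
    active = (weeks >= lo) & (weeks <= hi)
    if not active.any():
        return shape
    u = (weeks[active] - lo + 0.5) / (hi - lo + 1)
    s = np.sin(np.pi * u)
    if flat:
        s = s ** 0.25
    shape[active] = s / s.max()
    return shape


def _planted_trajectories(config: SimulationConfig, rng: np.random.Generator,
                          responsive: np.ndarray, sustained: np.ndarray,
                          signs: np.ndarray) -> dict:
    """Per-condition genes x weeks planted log2 fold-change matrices."""
    weeks = np.arange(1, config.n_weeks + 1)
    traj = {c: np.zeros((config.n_genes, weeks.size))
            for c in config.conditions if c != "control"}
    windows = {"preflowering": config.drought_weeks,
               "postflowering": config.postflowering_weeks}
    width = config.transient_width
    for g in np.flatnonzero(responsive):
        for cond, mat in traj.items():
            lo, hi = windows.get(cond, (weeks[0], weeks[-1]))
            lo, hi = max(lo, weeks[0]), min(hi, weeks[-1])
            if sustained[g]:
                shape = _window_shape(weeks, lo, hi, flat=True)
                if cond == "preflowering" and config.recovery_fraction > 0:
                    r_lo, r_hi = config.recovery_weeks
                    shape = shape + config.recovery_fraction * _window_shape(
                        weeks, max(r_lo, weeks[0]), min(r_hi, weeks[-1]), flat=True)
            else:
                w = min(width, hi - lo + 1)
                start = int(rng.integers(lo, hi - w + 2))
                shape = _window_shape(weeks, start, start + w - 1, flat=False)
            peak = np.abs(shape).max()
            if peak > 0:
                mat[g] = signs[g] * config.effect_size_log2 * shape / peak
    return {c: m for c, m in traj.items()}


def simulate_experiment(config: SimulationConfig) -> tuple:
    """Generate a counts experiment and its ground truth.

    Counts for gene g in sample s are NB(mu, dispersion) with
    ``mu = sf_s * 2^(baseline_g + trajectory_g[condition_s, week_s])``;
    the same config and seed reproduce the output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"gene{g:05d}" for g in range(n)], name="gene_id")

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=n)

    n_resp = round_half_up(config.frac_responsive * n)
    resp_idx = rng.choice(n, size=n_resp, replace=False)
    responsive = np.zeros(n, dtype=bool)
    responsive[resp_idx] = True
    n_sus = round_half_up(config.frac_sustained * n_resp)
    sus_idx = rng.choice(resp_idx, size=n_sus, replace=False) if n_resp else np.array([], int)
    sustained = np.zeros(n, dtype=bool)
    sustained[sus_idx.astype(int)] = True
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    signs[~responsive] = 0.0

    trajectories = _planted_trajectories(config, rng, responsive, sustained, signs)

    # design
    rows = []
    for genotype in config.genotypes:
        for condition in config.conditions:
            for week in range(1, config.n_weeks + 1):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{genotype}_{condition}_w{week:02d}_r{rep}"
                    rows.append((sid, genotype, config.tissue, condition, week, rep))
    design = pd.DataFrame(rows, columns=["sample_id", "genotype", "tissue",
                                         "condition", "week", "replicate"]
                          ).set_index("sample_id")

    sf_lo, sf_hi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), size=len(design)))

    log2_mu = np.tile(baseline[:, None], (1, len(design)))
    week_idx = design["week"].to_numpy() - 1
    for j, (cond) in enumerate(design["condition"].to_numpy()):
        if cond in trajectories:
            log2_mu[:, j] += trajectories[cond][:, week_idx[j]]
    mu = (2.0 ** log2_mu) * size_factors[None, :]

    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design.index)

    table = pd.DataFrame({
        "responsive": responsive,
        "sustained": sustained,
        "sign": signs.astype(int),
        "cellwall": np.zeros(n, dtype=bool),
    }, index=gene_ids)
    for cond, mat in trajectories.items():
        table[f"responsive_{cond}"] = np.abs(mat).max(axis=1) > 0
    weeks = np.arange(1, config.n_weeks + 1)
    truth = TruthTable(
        table=table,
        trajectories={c: pd.DataFrame(m, index=gene_ids, columns=weeks)
                      for c, m in trajectories.items()})
    return CountsExperiment(counts=counts_df, design=design), truth


# ---------------------------------------------------------------------------
# GO annotations

_SIM_FAMILIES = tuple(sorted({
    "cellulose synthase", "glycosyltransferase", "expansin",
    "xyloglucan endotransglucosylase/hydrolase", "peroxidase",
    "pectin methylesterase", "glycosyl hydrolase",
    "wall-associated kinase", "receptor-like kinase",
}))


def simulate_go_annotations(gene_ids, config: SimulationConfig,
                            truth: TruthTable | None = None) -> GOAnnotationSet:
    """Assign cell-wall GO terms, a curated list, and gene families.

    Exactly ``round_half_up(frac_cellwall_annotated * n)`` genes receive
    1-2 of the four cell-wall GO terms.  When a truth table is supplied,
    ``cellwall_responsive_overlap`` of the sustained responsive genes are
    annotated first (the planted cell-wall drought program); the
    remainder of the annotation budget is drawn from non-responsive
    genes, so the annotated/responsive overlap is fully controlled.  The
    curated list is a small disjoint set of unannotated genes.  The truth
    table's ``cellwall`` column is updated in place.
    """
    gene_ids = pd.Index(gene_ids)
    if gene_ids.has_duplicates:
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng([config.seed, 104729])
    n = len(gene_ids)
    n_cw = round_half_up(config.frac_cellwall_annotated * n)
    terms = sorted(CELL_WALL_GO_TERMS)

    chosen: list = []
    if truth is not None:
        sus = truth.table.index[truth.table["sustained"]]
        n_overlap = min(n_cw, round_half_up(
            config.cellwall_responsive_overlap * len(sus)))
        if n_overlap:
            pos = gene_ids.get_indexer(rng.choice(sus.to_numpy(), size=n_overlap,
                                                  replace=False))
            chosen.extend(int(i) for i in pos)
        pool = np.flatnonzero(~truth.table["responsive"].to_numpy())
    else:
        pool = np.arange(n)
    remaining = np.setdiff1d(pool, np.array(chosen, dtype=int))
    n_more = n_cw - len(chosen)
    if n_more > 0:
        chosen.extend(int(i) for i in rng.choice(remaining, size=n_more, replace=False))
    chosen = sorted(chosen)

    gene_to_terms: dict = {}
    for i in chosen:
        k = 1 + int(rng.random() < 0.3)
        picked = rng.choice(len(terms), size=k, replace=False)
        gene_to_terms[gene_ids[i]] = {terms[j] for j in picked}

    unannotated = np.setdiff1d(np.arange(n), np.array(chosen, dtype=int))
    n_curated = min(config.n_curated, unannotated.size)
    curated = {gene_ids[int(i)]
               for i in rng.choice(unannotated, size=n_curated, replace=False)}

    families = {}
    for gene in sorted(set(gene_to_terms) | curated):
        families[gene] = _SIM_FAMILIES[int(rng.integers(len(_SIM_FAMILIES)))]

    if truth is not None:
        cw = truth.table.index.isin(set(gene_to_terms) | curated)
        truth.table["cellwall"] = cw
    return GOAnnotationSet(gene_to_terms=gene_to_terms, curated=curated,
                           families=families)


# ---------------------------------------------------------------------------
# chemistry assays

def simulate_chem_dataset(config: ChemSimConfig) -> tuple:
    """Replicate-level analyte quantities with planted treatment effects.

    Each analyte x genotype x condition x week cell gets
    ``n_replicates`` values drawn log-normally (mean preserved, replicate
    CV = ``cv``) around ``control_mean * (1 + effect/100)``; the planted
    percent effect is looked up by ``(analyte, condition, week)`` and is
    zero for the control and for unlisted cells.  Returns the analyte
    table and a truth table of planted percent changes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 130363])
    sigma = math.sqrt(math.log(1.0 + config.cv ** 2)) if config.cv > 0 else 0.0
    rows = []
    truth_rows = []
    for analyte in config.analytes:
        base = config.control_mean(analyte)
        for genotype in config.genotypes:
            for condition in config.conditions:
                for week in config.weeks:
                    effect = 0.0 if condition == "control" else float(
                        config.planted_effects.get((analyte, condition, week), 0.0))
                    mean = base * (1.0 + effect / 100.0)
                    if sigma > 0:
                        vals = mean * np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                                        size=config.n_replicates))
                    else:
                        vals = np.full(config.n_replicates, mean)
                    for rep, v in enumerate(vals, start=1):
                        rows.append((analyte, config.tissue, genotype, condition,
                                     int(week), rep, float(v), config.units))
                    if condition != "control":
                        truth_rows.append((analyte, config.tissue, genotype,
                                           condition, int(week), effect))
    table = AnalyteTable(pd.DataFrame(rows, columns=[
        "analyte", "tissue", "genotype", "condition", "week", "replicate",
        "quantity", "units"]))
    truth = pd.DataFrame(truth_rows, columns=[
        "analyte", "tissue", "genotype", "condition", "week", "percent_effect"])
    return table, truth
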