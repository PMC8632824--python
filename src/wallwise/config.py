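"""Configuration objects for the simulator and the pipeline.

All configs are plain dataclasses with YAML round-trip helpers.  Every
stochastic component takes its randomness from the single integer ``seed``
of the config that drives it, so a config fully determines the output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Week windows (inclusive) of the irrigation regimes: watering is withheld
#: during weeks 3-8 for the pre-flowering drought (followed by re-watering
#: and recovery through week 17) and during weeks 10-17 for the
#: post-flowering drought.
DROUGHT_WEEKS = (3, 8)
RECOVERY_WEEKS = (9, 17)
POSTFLOWERING_WEEKS = (10, 17)


@dataclass
class SimulationConfig:
    """Design and statistical parameters of the synthetic RNA-seq experiment.

    Defaults mirror the field design being emulated: two genotypes
    (pre-flowering drought tolerant RTx430, post-flowering drought tolerant
    BTx642), three irrigation conditions, 17 weekly time points and three
    replicate plots per genotype x condition, for one tissue at a time.

    Parameters
    ----------
    n_genes : int
        Number of simulated genes.
    n_weeks : int
        Number of weekly time points; weeks are numbered ``1..n_weeks``.
    frac_responsive : float
        Proportion of genes given a planted drought-response trajectory.
    frac_sustained : float
        Proportion of the responsive genes whose response is *sustained*
        across the whole stress window (these emulate the core cell-wall
        drought program and are preferentially cell-wall annotated by
        :func:`wallwise.simulate.simulate_go_annotations`); the remainder
        respond transiently in a short sub-window.
    effect_size_log2 : float
        Peak absolute log2 fold change of every planted trajectory.
    recovery_fraction : float
        Relative amplitude, during the re-watering weeks, of the sustained
        pre-flowering response (0 = full recovery immediately on
        re-watering).
    dispersion : float
        Negative-binomial dispersion (variance = mu + dispersion * mu^2).
    baseline_log_mean_range : tuple
        Per-gene baseline expression drawn log2-uniform over this range.
    size_factor_range : tuple
        Per-sample library size factors drawn log-uniform over this range,
        so that upper-quartile normalization has real work to do.
    frac_cellwall_annotated : float
        Proportion of genes receiving at least one cell-wall GO term.
    cellwall_responsive_overlap : float
        Proportion of the cell-wall annotated genes drawn from the
        sustained responsive set (the rest are non-responsive).
    transient_width : int
        Width in weeks of the transient response bump.
    """

    n_genes: int = 2000
    n_weeks: int = 17
    genotypes: tuple = ("RTx430", "BTx642")
    conditions: tuple = ("control", "preflowering", "postflowering")
    n_replicates: int = 3
    tissue: str = "leaf"
    frac_responsive: float = 0.1
    frac_sustained: float = 0.2
    effect_size_log2: float = 2.0
    recovery_fraction: float = 0.5
    dispersion: float = 0.1
    baseline_log_mean_range: tuple = (2.0, 9.0)
    size_factor_range: tuple = (0.7, 1.4)
    frac_cellwall_annotated: float = 0.1
    cellwall_responsive_overlap: float = 1.0
    n_curated: int = 5
    drought_weeks: tuple = DROUGHT_WEEKS
    recovery_weeks: tuple = RECOVERY_WEEKS
    postflowering_weeks: tuple = POSTFLOWERING_WEEKS
    transient_width: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_replicates, int) or isinstance(self.n_replicates, bool):
            raise TypeError(f"replicate count must be an integer, got {self.n_replicates!r}")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates are required")
        if self.n_genes < 1 or self.n_weeks < 1:
            raise ValueError("n_genes and n_weeks must be positive")
        for name in ("frac_responsive", "frac_sustained", "frac_cellwall_annotated",
                     "cellwall_responsive_overlap", "recovery_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if "control" not in self.conditions:
            raise ValueError("conditions must contain 'control'")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


# Percent increases in leaf matrix monosaccharides reported for the
# pre-flowering drought at the week-7 sampling: these serve as realistic
# planted effect sizes for the chemistry simulator.
DEFAULT_CHEM_EFFECTS: dict = {
    ("rhamnose", "preflowering", 7): 62.0,
    ("arabinose", "preflowering", 7): 33.0,
    ("glucose", "preflowering", 7): 62.0,
    ("galacturonic_acid", "preflowering", 7): 37.0,
}


@dataclass
class ChemSimConfig:
    """Design of the synthetic chemistry assay dataset.

    Replicate measurements are drawn log-normally around
    ``control_mean * (1 + effect/100)`` with coefficient of variation
    ``cv``; ``planted_effects`` maps ``(analyte, condition, week)`` to a
    percent change relative to the watered control.
    """

    analytes: tuple = ("rhamnose", "arabinose", "glucose", "galacturonic_acid")
    weeks: tuple = (7, 14)
    conditions: tuple = ("control", "preflowering", "postflowering")
    genotypes: tuple = ("RTx430",)
    tissue: str = "leaf"
    n_replicates: int = 3
    control_means: Mapping[str, float] = field(default_factory=dict)
    default_control_mean: float = 10.0
    planted_effects: Mapping[tuple, float] = field(
        default_factory=lambda: dict(DEFAULT_CHEM_EFFECTS))
    cv: float = 0.1
    units: str = "ug_per_mg_AIR"
    seed: int = 0

    def validate(self) -> None:
        if self.cv < 0:
            raise ValueError("replicate CV must be nonnegative")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates are required")
        if "control" not in self.conditions:
            raise ValueError("conditions must contain 'control'")

    def control_mean(self, analyte: str) -> float:
        return float(self.control_means.get(analyte, self.default_control_mean))


@dataclass
class AnalysisParams:
    """Tunable parameters of the transcriptome analysis stages."""

    min_mean: float = 1.0          # low-expression filter, mean counts
    spline_df: int = 4             # natural cubic spline degrees of freedom
    hvg_fraction: float = 0.05     # top/bottom quantile for HVG labeling
    alpha: float = 0.05            # eligibility threshold on adjusted p
    lfc_mode: str = "signed_mean"  # ranking statistic variant
    trend_band: float = 0.25       # |mean L| below this => "no change"
    focus_weeks: tuple = (7, 14)
    fdr: float = 0.25              # chemistry BH decision threshold
    chem_alpha: float = 0.05


@dataclass
class RunConfig:
    """Top-level pipeline configuration (simulation + analysis + chemistry)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    chem: ChemSimConfig = field(default_factory=ChemSimConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def __post_init__(self):
        # the run seed overrides the per-section seeds so one integer
        # determines the whole run
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.chem = dataclasses.replace(self.chem, seed=self.seed + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chem"]["planted_effects"] = [
            {"analyte": a, "condition": c, "week": int(w), "percent": float(v)}
            for (a, c, w), v in self.chem.planted_effects.items()
        ]
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = _build(SimulationConfig, raw.get("simulation", {}))
        chem_raw = dict(raw.get("chem", {}))
        if isinstance(chem_raw.get("planted_effects"), list):
            chem_raw["planted_effects"] = {
                (e["analyte"], e["condition"], int(e["week"])): float(e["percent"])
                for e in chem_raw["planted_effects"]
            }
        chem = _build(ChemSimConfig, chem_raw)
        params = _build(AnalysisParams, raw.get("params", {}))
        return cls(simulation=sim, chem=chem, params=params, seed=int(raw.get("seed", 0)))


def _build(cls, section: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in kw and isinstance(f.default, tuple) and isinstance(kw[f.name], list):
            kw[f.name] = tuple(kw[f.name])
    return cls(**kw)


def _plain(obj):
    """Recursively convert tuples to lists so YAML output is plain types."""
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else str(list(k))): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
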