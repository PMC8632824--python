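"""Analytical-chemistry quantification.

Three quantification layers used on cell-wall preparations (alcohol
insoluble residue, AIR):

* linear calibration curves for chromatographic monosaccharide /
  hydroxycinnamate signals (standards spanning 2.5-200 uM) and for the
  DNS reducing-sugar assay (glucose standards, 0-2 mg);
* acetyl-bromide soluble lignin (%ABSL) from A280 via Beer-Lambert with
  a commelinid-average extinction coefficient;
* saccharification efficiency: net glucose-equivalent release over a
  72-h enzymatic digestion, from DNS readings at 0/24/48/72 h.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Average extinction coefficient (g^-1 L cm^-1) of known commelinid
#: monocot lignins, used for acetyl-bromide soluble lignin.
COMMELINID_EXTINCTION_COEFF = 18.19509

ANALYTE_COLUMNS = ("analyte", "tissue", "genotype", "condition", "week",
                   "replicate", "quantity", "units")


@dataclass
class AnalyteTable:
    """Long-format replicate-level analyte quantities (per mg AIR)."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(ANALYTE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"analyte table lacks columns: {sorted(missing)}")
        if (self.data["quantity"] < 0).any():
            raise ValueError("analyte quantities must be nonnegative")
        if self.data["units"].nunique() > 1:
            raise ValueError(
                f"mixed units in analyte table: {sorted(self.data['units'].unique())}")
        dup = self.data.duplicated(
            subset=["analyte", "tissue", "genotype", "condition", "week", "replicate"])
        if dup.any():
            raise ValueError("duplicate replicate labels within a design cell")

    @property
    def units(self) -> str:
        return str(self.data["units"].iloc[0])

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AnalyteTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CalibrationCurve:
    """Ordinary least-squares line through (standard level, signal) pairs."""

    analyte: str
    levels: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    units: str = "uM"

    @property
    def valid_range(self) -> tuple:
        return float(np.min(self.levels)), float(np.max(self.levels))


def fit_calibration(levels, responses, analyte: str = "", units: str = "uM",
                    r2_warn: float = 0.99) -> CalibrationCurve:
    """Fit a linear standard curve by unweighted OLS.

    Requires >= 3 distinct standard levels; warns when R^2 falls below
    ``r2_warn`` (poorly linear standards).
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if levels.size < 3:
        raise ValueError("calibration requires at least 3 standards")
    if np.unique(levels).size < 2:
        raise ValueError("standard levels must not be identical")
    res = stats.linregress(levels, responses)
    r2 = float(res.rvalue ** 2)
    if res.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    if r2 < r2_warn:
        warnings.warn(f"calibration R^2 = {r2:.4f} below {r2_warn} for {analyte or 'analyte'}",
                      stacklevel=2)
    return CalibrationCurve(analyte=analyte, levels=levels, responses=responses,
                            slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, units=units)


@dataclass
class QuantResult:
    """Quantity per mg plus per-value QC flags."""

    value: np.ndarray           # analyte level per mg sample
    level: np.ndarray           # back-calculated level before mass normalization
    extrapolated: np.ndarray    # outside [0.5x, 2x] the calibration range
    clamped: np.ndarray         # negative back-calculated level floored at 0


def quantify(signal, curve: CalibrationCurve, dilution: float = 1.0,
             sample_mass: float = 1.0) -> QuantResult:
    """Invert a calibration curve: signal -> analyte level -> quantity per mg.

    ``level = (signal - intercept) / slope * dilution``; values outside
    0.5x-2x the standard range are flagged as extrapolated, negative
    levels are clamped to zero with a flag.
    """
    if sample_mass <= 0:
        raise ValueError("sample mass must be positive")
    signal = np.atleast_1d(np.asarray(signal, dtype=float))
    level = (signal - curve.intercept) / curve.slope * dilution
    lo, hi = curve.valid_range
    extrapolated = (level < 0.5 * lo) | (level > 2.0 * hi)
    clamped = level < 0
    level = np.where(clamped, 0.0, level)
    return QuantResult(value=level / sample_mass, level=level,
                       extrapolated=extrapolated, clamped=clamped)


@dataclass
class LigninAssay:
    """Inputs of an acetyl-bromide lignin determination.

    ``a280`` is the absorbance of the digest at 280 nm, ``sample_mass_g``
    the AIR mass digested, ``volume_l`` the extract volume, and
    ``extinction`` the lignin extinction coefficient in g^-1 L cm^-1.
    """

    a280: float
    sample_mass_g: float
    volume_l: float
    path_cm: float = 1.0
    extinction: float = COMMELINID_EXTINCTION_COEFF

    def __post_init__(self):
        if self.sample_mass_g <= 0 or self.volume_l <= 0 or self.path_cm <= 0:
            raise ValueError("mass, volume and path length must be positive")
        if self.a280 < 0:
            raise ValueError("absorbance must be nonnegative")


def acetyl_bromide_lignin(assay: LigninAssay) -> float:
    """Percent acetyl-bromide soluble lignin (% w/w).

    Beer-Lambert: lignin concentration (g/L) = A280 / (epsilon * path);
    total lignin = concentration * extract volume; expressed as percent
    of the digested sample mass.
    """
    conc_g_per_l = assay.a280 / (assay.extinction * assay.path_cm)
    return 100.0 * conc_g_per_l * assay.volume_l / assay.sample_mass_g


@dataclass
class SaccharificationResult:
    """Net glucose-equivalent release per mg biomass over the digestion."""

    times_h: np.ndarray
    release_per_mg: np.ndarray   # net of the T0 reading, floored at 0
    raw_per_mg: np.ndarray
    floored: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h,
                             "release_per_mg": self.release_per_mg,
                             "raw_per_mg": self.raw_per_mg,
                             "floored": self.floored})


def saccharification_efficiency(times_h, signals, glucose_curve: CalibrationCurve,
                                sample_mass_mg: float) -> SaccharificationResult:
    """Quantify a DNS reducing-sugar time series against glucose standards.

    The reading at time zero (pre-incubation background) is subtracted
    from each later timepoint; negative net release is floored at zero
    and flagged.  Missing readings (NaN) propagate as NaN.
    """
    times_h = np.asarray(times_h, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if times_h.size != signals.size:
        raise ValueError("times and signals must align")
    order = np.argsort(times_h)
    times_h, signals = times_h[order], signals[order]
    if times_h[0] != 0:
        raise ValueError("a T0 (time zero) reading is required")
    quant = quantify(signals, glucose_curve, sample_mass=sample_mass_mg)
    raw = quant.value
    net = raw - raw[0]
    floored = net < 0
    net = np.where(np.isnan(net), np.nan, np.where(floored, 0.0, net))
    if np.any(floored & ~np.isnan(signals)):
        log.info("floored %d negative net-release values at 0",
                 int(np.sum(floored & ~np.isnan(signals))))
    return SaccharificationResult(times_h=times_h, release_per_mg=net,
                                  raw_per_mg=raw, floored=floored)
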