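"""Treatment-vs-control statistics on analyte tables.

For every analyte x tissue x genotype x week, each drought condition is
compared with the watered control of the same week by a two-sided pooled
(Student) t-test; p-values are Benjamini-Hochberg corrected within a
configurable family (default: all analytes of one tissue x genotype x
week report) and reported alongside the percent change.  The decision
rule follows the dual convention of reporting both a raw p < 0.05
threshold and survival of BH at a conservative FDR of 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chem import AnalyteTable
from .hvg import bh_adjust

log = logging.getLogger(__name__)

DEGENERATE_NONE = ""
DEGENERATE_ZERO_VAR = "degenerate"


def contrast_ttest(treatment, control) -> tuple:
    """Two-sided two-sample pooled-variance Student t-test.

    Returns ``(t, p, flag)``.  With zero pooled variance the test is
    degenerate: equal means give ``(0, 1)``, unequal means give
    ``(+/-inf, 0)`` with the ``"degenerate"`` flag.
    """
    t_arr = np.asarray(treatment, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise ValueError("at least 2 replicates per group are required")
    n1, n2 = t_arr.size, c_arr.size
    sp2 = (((n1 - 1) * t_arr.var(ddof=1) + (n2 - 1) * c_arr.var(ddof=1))
           / (n1 + n2 - 2))
    if sp2 == 0:
        if t_arr.mean() == c_arr.mean():
            return 0.0, 1.0, DEGENERATE_NONE
        return float(np.sign(t_arr.mean() - c_arr.mean()) * np.inf), 0.0, DEGENERATE_ZERO_VAR
    res = stats.ttest_ind(t_arr, c_arr, equal_var=True)
    return float(res.statistic), float(res.pvalue), DEGENERATE_NONE


def flag_outliers(values, k: float = 4.0) -> np.ndarray:
    """Keep-mask for replicate values; drops at most one extreme outlier.

    A replicate is an outlier when its absolute deviation from the mean of
    the *other* replicates exceeds ``k`` times their standard deviation.
    Nothing is removed with fewer than 3 replicates, and never below 2
    survivors; if several replicates qualify only the most extreme one is
    dropped.  Removals are logged.
    """
    v = np.asarray(values, dtype=float)
    keep = np.ones(v.size, dtype=bool)
    if v.size < 3:
        return keep
    scores = np.full(v.size, np.nan)
    for i in range(v.size):
        others = np.delete(v, i)
        sd = others.std(ddof=1)
        if sd == 0:
            continue
        scores[i] = abs(v[i] - others.mean()) / sd
    exceeds = scores > k
    if exceeds.any():
        worst = int(np.nanargmax(np.where(exceeds, scores, np.nan)))
        keep[worst] = False
        log.info("removed outlier replicate %d (value %.4g, score %.2f x SD)",
                 worst, v[worst], scores[worst])
    return keep


@dataclass
class ContrastOptions:
    alpha: float = 0.05
    fdr: float = 0.25
    family: tuple = ("tissue", "genotype", "week")
    outlier_k: float | None = None   # None disables outlier screening


def contrast_table(table: AnalyteTable, options: ContrastOptions | None = None) -> pd.DataFrame:
    """All drought-vs-control contrasts in an analyte table.

    Returns one row per analyte x tissue x genotype x week x drought
    condition with group means/SDs, percent change, t, raw p, BH-adjusted
    p (within the configured family) and the significance decision.
    Contrasts lacking a control cell are skipped with a log entry.
    """
    options = options or ContrastOptions()
    df = table.data
    rows = []
    keys = ["analyte", "tissue", "genotype", "week"]
    for key_vals, cell in df.groupby(keys, sort=True):
        by_cond = {c: g["quantity"].to_numpy() for c, g in cell.groupby("condition")}
        if "control" not in by_cond:
            log.warning("no control cell for %s; contrasts skipped", key_vals)
            continue
        ctrl = by_cond["control"]
        if options.outlier_k is not None:
            ctrl = ctrl[flag_outliers(ctrl, options.outlier_k)]
        for cond in sorted(by_cond):
            if cond == "control":
                continue
            trt = by_cond[cond]
            if options.outlier_k is not None:
                trt = trt[flag_outliers(trt, options.outlier_k)]
            t, p, flag = contrast_ttest(trt, ctrl)
            cmean = ctrl.mean()
            rows.append(dict(zip(keys, key_vals)) | {
                "condition": cond,
                "control_mean": cmean, "control_sd": ctrl.std(ddof=1),
                "treatment_mean": trt.mean(), "treatment_sd": trt.std(ddof=1),
                "percent_change": (100.0 * (trt.mean() - cmean) / cmean
                                   if cmean != 0 else np.nan),
                "t": t, "p": p, "flag": flag,
                "n_treatment": trt.size, "n_control": ctrl.size,
            })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    return adjust_and_flag(result, alpha=options.alpha, fdr=options.fdr,
                           family=options.family)


def adjust_and_flag(contrasts: pd.DataFrame, alpha: float = 0.05, fdr: float = 0.25,
                    family: tuple = ("tissue", "genotype", "week")) -> pd.DataFrame:
    """Attach BH-adjusted p-values and significance decisions.

    Adjustment is applied within each family group (default: per tissue x
    genotype x week report across analytes and conditions).  A contrast is
    significant when its raw p < ``alpha`` *and* it survives BH at the
    configured FDR (adjusted p < ``fdr``).
    """
    if contrasts.empty:
        raise ValueError("empty contrast family")
    out = contrasts.copy()
    family_cols = [c for c in family if c in out.columns]
    if family_cols:
        adj = np.empty(len(out))
        for _, idx in out.groupby(family_cols, sort=False).groups.items():
            adj[out.index.get_indexer(idx)] = bh_adjust(out.loc[idx, "p"].to_numpy())
        out["p_adjusted"] = adj
    else:
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p"] < alpha) & (out["p_adjusted"] < fdr)
    return out
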