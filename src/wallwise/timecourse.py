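"""Per-gene smooth time-course models and moderated differential-expression
statistics.

Expression (log2 of normalized counts plus one) is modeled as a smooth
function of week using a natural cubic spline basis, with a separate
functional form per watering condition: the full model for a
control/drought pair within one genotype is

    y = b0 + f(week) + condition + condition : f(week) + error,

fit gene-wise by least squares; the null model drops every condition
term.  The per-week log2 fold-change trajectory L is the difference of
the two fitted curves.  Residual variances are moderated across genes by
an empirical-Bayes scheme (moment matching on log s^2), and the
condition effect is tested with a moderated F statistic referred to
F(q, d0 + d).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import NormalizedMatrix

log = logging.getLogger(__name__)

#: d0 value used to represent "effectively infinite" prior degrees of
#: freedom (full shrinkage to the prior variance).
D0_CAP = 1e6


# ---------------------------------------------------------------------------
# spline basis

def _natural_spline(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (linear beyond the
    boundary knots); ``len(knots) - 1`` columns including the linear term."""
    K = len(knots)

    def d(k):
        return ((np.clip(x - knots[k], 0, None) ** 3
                 - np.clip(x - knots[-1], 0, None) ** 3) / (knots[-1] - knots[k]))

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


@dataclass
class SplineBasis:
    """Natural cubic spline basis over the assay weeks.

    ``df`` columns; ``df = 1`` degenerates to a centered linear term.
    Knots sit at quantiles of the distinct times with boundary knots at
    their extremes.  Columns are centered with constants fixed at
    construction so evaluation at new times is consistent.
    """

    times: np.ndarray
    df: int
    knots: np.ndarray
    matrix: np.ndarray
    col_means: np.ndarray

    @property
    def boundary_knots(self) -> tuple:
        return float(self.knots[0]), float(self.knots[-1])

    def evaluate(self, new_times) -> np.ndarray:
        x = np.asarray(new_times, dtype=float)
        if self.df == 1:
            return x[:, None] - self.col_means
        return _natural_spline(x, self.knots) - self.col_means


def build_spline_basis(times, df: int = 4) -> SplineBasis:
    """Construct a natural cubic spline basis evaluated at ``times``.

    Requires strictly more distinct times than ``df``.
    """
    t = np.asarray(times, dtype=float)
    distinct = np.unique(t)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df >= distinct.size:
        raise ValueError(f"df={df} requires more than {df} distinct times, "
                         f"got {distinct.size}")
    if df == 1:
        knots = np.array([distinct[0], distinct[-1]])
        raw = t[:, None]
    else:
        knots = np.quantile(distinct, np.linspace(0, 1, df + 1))
        raw = _natural_spline(t, knots)
    col_means = raw.mean(axis=0)
    return SplineBasis(times=t, df=df, knots=knots,
                       matrix=raw - col_means, col_means=col_means)


# ---------------------------------------------------------------------------
# gene-wise fits

@dataclass
class GeneFits:
    """Least-squares fits of the full and null time-course models for a
    set of genes sharing one design."""

    gene_ids: pd.Index
    genotype: str
    condition: str
    rss_full: np.ndarray
    rss_null: np.ndarray
    df_resid: int
    q: int                      # number of condition-related parameters
    s2: np.ndarray              # residual variance, rss_full / df_resid
    weeks: np.ndarray           # shared assayed weeks
    L: pd.DataFrame             # genes x weeks fitted log2 fold changes
    curves: dict                # condition -> genes x weeks fitted curves
    na_mask: np.ndarray         # genes with NA fits


def fit_gene_models(norm: NormalizedMatrix, basis: SplineBasis,
                    contrast: tuple, genotype: str,
                    week_range: tuple | None = None) -> GeneFits:
    """Fit per-gene full and null models for one condition pair and genotype.

    Parameters
    ----------
    contrast : tuple
        ``(control_condition, drought_condition)``; the second level is
        the one whose indicator enters the model.
    week_range : tuple, optional
        Inclusive ``(lo, hi)`` week window restricting the fit (used for
        the pre-flowering drought-only and recovery-only sub-periods).

    The L trajectory is the full-model fitted drought curve minus the
    fitted control curve at each shared week.
    """
    control, drought = contrast
    design = norm.design
    mask = (design["genotype"] == genotype) & design["condition"].isin([control, drought])
    if week_range is not None:
        lo, hi = week_range
        mask &= (design["week"] >= lo) & (design["week"] <= hi)
    sub = design[mask]
    for cond in (control, drought):
        if not (sub["condition"] == cond).any():
            raise ValueError(f"condition {cond!r} absent for genotype {genotype!r}")
    Y = norm.log2.loc[:, sub.index].to_numpy()
    weeks = sub["week"].to_numpy(dtype=float)
    ind = (sub["condition"] == drought).to_numpy(dtype=float)

    B = basis.evaluate(weeks)
    ones = np.ones((len(sub), 1))
    X_null = np.hstack([ones, B])
    X_full = np.hstack([ones, B, ind[:, None], ind[:, None] * B])
    q = X_full.shape[1] - X_null.shape[1]
    df_resid = len(sub) - X_full.shape[1]
    n_genes = Y.shape[0]

    if df_resid <= 0 or np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        log.warning("singular or saturated design for %s/%s (%s); NA fits",
                    genotype, drought, week_range)
        nan_vec = np.full(n_genes, np.nan)
        uw = np.unique(weeks)
        nan_mat = pd.DataFrame(np.full((n_genes, uw.size), np.nan),
                               index=norm.log2.index, columns=uw.astype(int))
        return GeneFits(gene_ids=norm.log2.index, genotype=genotype, condition=drought,
                        rss_full=nan_vec, rss_null=nan_vec.copy(),
                        df_resid=max(df_resid, 0), q=q, s2=nan_vec.copy(),
                        weeks=uw, L=nan_mat, curves={},
                        na_mask=np.ones(n_genes, dtype=bool))

    rss_full, beta_full = _lstsq_rss(X_full, Y)
    rss_null, _ = _lstsq_rss(X_null, Y)
    # nesting can be violated only by round-off; clamp
    rss_null = np.maximum(rss_null, rss_full)

    uw = np.unique(weeks)
    Bp = basis.evaluate(uw)
    onesp = np.ones((uw.size, 1))
    zeros = np.zeros((uw.size, 1))
    X_ctrl = np.hstack([onesp, Bp, zeros, np.zeros_like(Bp)])
    X_drt = np.hstack([onesp, Bp, onesp, Bp])
    curve_ctrl = (X_ctrl @ beta_full).T
    curve_drt = (X_drt @ beta_full).T
    weeks_int = uw.astype(int)
    L = pd.DataFrame(curve_drt - curve_ctrl, index=norm.log2.index, columns=weeks_int)
    curves = {control: pd.DataFrame(curve_ctrl, index=norm.log2.index, columns=weeks_int),
              drought: pd.DataFrame(curve_drt, index=norm.log2.index, columns=weeks_int)}
    return GeneFits(gene_ids=norm.log2.index, genotype=genotype, condition=drought,
                    rss_full=rss_full, rss_null=rss_null, df_resid=df_resid, q=q,
                    s2=rss_full / df_resid, weeks=uw, L=L, curves=curves,
                    na_mask=np.zeros(n_genes, dtype=bool))


def _lstsq_rss(X: np.ndarray, Y: np.ndarray) -> tuple:
    """Least-squares fit of every row of Y on X; returns (rss per gene, beta)."""
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return np.einsum("ij,ij->j", resid, resid), beta


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

@dataclass
class ModerationParams:
    """Empirical-Bayes prior and the per-gene moderated variances.

    ``s2_tilde = (d0 * s0^2 + d * s2) / (d0 + d)`` lies between each
    gene's s^2 and the prior s0^2; ``d0 >= D0_CAP`` encodes full
    shrinkage (the observed variances are consistent with a single s0^2).
    """

    d0: float
    s0_squared: float
    s2_tilde: np.ndarray
    residual_df: int


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(60):
        f = special.polygamma(1, x) - y
        fprime = special.polygamma(2, x)
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10 * (1 + abs(x)):
            x = x_new
            break
        x = x_new
    return float(x)


def moderate_variances(s2, residual_df: int) -> ModerationParams:
    """Estimate the variance prior by moment matching on log s^2.

    Under the hierarchical scaled-inverse-chi-square model the variance
    of log s^2 across genes equals ``trigamma(d/2) + trigamma(d0/2)``;
    the excess over ``trigamma(d/2)`` is inverted numerically for d0.
    When the empirical variance does not exceed ``trigamma(d/2)`` the
    prior degrees of freedom are capped at ``D0_CAP`` (full shrinkage).
    With fewer than 10 genes moderation is skipped (d0 = 0).
    """
    s2 = np.asarray(s2, dtype=float)
    if residual_df < 1:
        raise ValueError("residual df must be >= 1")
    if np.any(s2 < 0):
        raise ValueError("variances must be nonnegative")
    d = float(residual_df)
    if s2.size < 10:
        warnings.warn("fewer than 10 genes: variance moderation skipped",
                      stacklevel=2)
        return ModerationParams(d0=0.0, s0_squared=float(np.median(s2)),
                                s2_tilde=s2.copy(), residual_df=residual_df)
    z = np.log(np.clip(s2, np.finfo(float).tiny, None))
    emp_var = float(np.var(z, ddof=1))
    base = float(special.polygamma(1, d / 2))
    excess = emp_var - base
    if excess <= 0:
        d0 = D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, D0_CAP)
    # E[log s^2] = log s0^2 + (psi(d/2) - log(d/2)) - (psi(d0/2) - log(d0/2))
    log_s0 = (float(np.mean(z))
              - (special.digamma(d / 2) - np.log(d / 2))
              + (special.digamma(d0 / 2) - np.log(d0 / 2)))
    s0_squared = float(np.exp(log_s0))
    s2_tilde = (d0 * s0_squared + d * s2) / (d0 + d)
    return ModerationParams(d0=float(d0), s0_squared=s0_squared,
                            s2_tilde=s2_tilde, residual_df=residual_df)


# ---------------------------------------------------------------------------
# moderated F statistics

@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast."""

    genotype: str
    condition: str
    window: str
    table: pd.DataFrame      # gene_id, genotype, condition, window, F, p
    L: pd.DataFrame          # genes x weeks log2 fold-change trajectories

    def write_tsv(self, path) -> None:
        wide = self.table.set_index("gene_id").join(
            self.L.rename(columns=lambda w: f"L_{w}"))
        wide.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path) -> "DEResult":
        wide = pd.read_csv(path, sep="\t", index_col="gene_id")
        l_cols = [c for c in wide.columns if c.startswith("L_")]
        L = wide[l_cols].rename(columns=lambda c: int(c[2:]))
        table = wide.drop(columns=l_cols).reset_index()
        return cls(genotype=str(table["genotype"].iloc[0]),
                   condition=str(table["condition"].iloc[0]),
                   window=str(table["window"].iloc[0]), table=table, L=L)


def compute_de_stats(fits: GeneFits, moderation: ModerationParams,
                     window: str = "full") -> DEResult:
    """Moderated F statistics and p-values for one fitted contrast.

    ``F = ((RSS0 - RSS1)/q) / s2_tilde`` referred to F(q, d0 + d); genes
    where both numerator and moderated variance vanish (no signal, no
    noise) receive F = 0, p = 1.  NA fits propagate NA p-values.
    """
    num = (fits.rss_null - fits.rss_full) / fits.q
    denom = moderation.s2_tilde
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0),
                     np.where(num > 0, np.inf, 0.0))
    dfd = min(moderation.d0 + moderation.residual_df, D0_CAP)
    p = stats.f.sf(F, fits.q, dfd)
    p = np.where(np.isnan(fits.rss_full), np.nan, p)
    F = np.where(np.isnan(fits.rss_full), np.nan, F)
    n_na = int(np.isnan(p).sum())
    if n_na:
        log.info("%d genes with NA statistics in %s/%s", n_na, fits.genotype,
                 fits.condition)
    table = pd.DataFrame({
        "gene_id": fits.gene_ids, "genotype": fits.genotype,
        "condition": fits.condition, "window": window, "F": F, "p": p})
    return DEResult(genotype=fits.genotype, condition=fits.condition,
                    window=window, table=table, L=fits.L)


# ---------------------------------------------------------------------------
# orchestration over contrasts

def run_contrasts(norm: NormalizedMatrix, spline_df: int = 4,
                  drought_weeks: tuple = (3, 8),
                  recovery_weeks: tuple = (9, 17),
                  control: str = "control") -> dict:
    """Fit every condition x genotype x period contrast in a dataset.

    For each drought condition and genotype the full course is fitted;
    the pre-flowering condition is additionally fitted on the
    drought-only and recovery-only week windows.  Returns
    ``(condition, window, genotype) -> DEResult``.
    """
    design = norm.design
    genotypes = sorted(design["genotype"].unique())
    conditions = [c for c in design["condition"].unique() if c != control]
    results: dict = {}
    for condition in sorted(conditions):
        windows = {"full": None}
        if condition == "preflowering":
            windows["drought"] = drought_weeks
            windows["recovery"] = recovery_weeks
        for window, week_range in windows.items():
            for genotype in genotypes:
                sel = design["condition"].isin([control, condition]) \
                    & (design["genotype"] == genotype)
                weeks = design.loc[sel, "week"]
                if week_range is not None:
                    weeks = weeks[(weeks >= week_range[0]) & (weeks <= week_range[1])]
                if weeks.empty:
                    log.warning("no samples for %s/%s/%s; list will be empty",
                                condition, window, genotype)
                    continue
                df_eff = min(spline_df, weeks.nunique() - 1)
                basis = build_spline_basis(np.unique(weeks), df=df_eff)
                fits = fit_gene_models(norm, basis, (control, condition),
                                       genotype, week_range=week_range)
                mod = moderate_variances(fits.s2, fits.df_resid) \
                    if not fits.na_mask.all() else ModerationParams(
                        0.0, float("nan"), fits.s2, max(fits.df_resid, 1))
                results[(condition, window, genotype)] = compute_de_stats(
                    fits, mod, window=window)
    return results


def genotype_contrast(norm: NormalizedMatrix, spline_df: int = 4,
                      conditions: tuple | None = None) -> dict:
    """Differential expression between the two genotypes.

    The same spline machinery with genotype as the two-level factor,
    fitted within each condition; results are keyed by condition and the
    L trajectory is genotype 2 minus genotype 1 (lexical order).  This
    sits outside the HVG path but is exposed for completeness.
    """
    design = norm.design
    genotypes = sorted(design["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError("genotype contrast requires exactly two genotypes")
    conditions = conditions or tuple(sorted(design["condition"].unique()))
    results = {}
    for condition in conditions:
        sub_idx = design.index[design["condition"] == condition]
        sub_design = design.loc[sub_idx].copy()
        # reuse the condition machinery by relabeling genotype as the factor
        relabeled = sub_design.assign(condition=sub_design["genotype"],
                                      genotype="pooled")
        sub_norm = NormalizedMatrix(values=norm.values.loc[:, sub_idx],
                                    size_factors=norm.size_factors.loc[sub_idx],
                                    design=relabeled,
                                    pseudocount=norm.pseudocount)
        weeks = relabeled["week"]
        df_eff = min(spline_df, weeks.nunique() - 1)
        basis = build_spline_basis(np.unique(weeks), df=df_eff)
        fits = fit_gene_models(sub_norm, basis, (genotypes[0], genotypes[1]), "pooled")
        mod = moderate_variances(fits.s2, fits.df_resid)
        res = compute_de_stats(fits, mod, window="full")
        res.table["condition"] = condition
        results[condition] = res
    return results
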