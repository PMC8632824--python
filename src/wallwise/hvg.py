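"""Highly-variable-gene (HVG) selection.

Per drought condition, the two genotypes' time-course p-values are
combined by Fisher's method (-2 sum ln p ~ chi^2 with 2k df), corrected by
Benjamini-Hochberg, and genes with adjusted p < 0.05 are ranked by the
overall log-fold change across the course, lfc = mean_t L_t; the top 5%
and bottom 5% of the ranking form one labeled list.  Four full-course
lists (2 genotypes x 2 drought conditions) plus four pre-flowering
sub-period lists (drought-only and recovery-only weeks) are merged into a
per-tissue HVG set.

Note on the ranking statistic: written literally as
sign(mean L) x (mean L) the overall fold change is the *absolute* mean,
which admits no "bottom" tail; the signed mean is therefore the default
ranking statistic, and the literal absolute-value form remains available
as ``mode="as_printed"``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


def fisher_combine(pvalues) -> tuple:
    """Combine p-values by Fisher's method.

    Accepts a 1-D vector (one gene, k p-values) or a 2-D array of shape
    (n_genes, k) and returns ``(X2, combined_p)`` with matching shape.
    ``X2 = -2 sum ln p`` is referred to chi^2 with 2k degrees of freedom.
    Zero p-values are clamped to the smallest positive float with a
    warning.
    """
    p = np.asarray(pvalues, dtype=float)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] < 1:
        raise ValueError("at least one p-value is required")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-values clamped to the smallest positive float",
                      stacklevel=2)
        p = np.clip(p, _TINY, 1.0)
    x2 = -2.0 * np.log(p).sum(axis=1)
    combined = stats.chi2.sf(x2, 2 * p.shape[1])
    if squeeze:
        return float(x2[0]), float(combined[0])
    return x2, combined


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input order is preserved; values are clipped at 1 and monotone in the
    ranking.  NaN entries propagate as NaN and are excluded from the
    number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def overall_lfc(L, mode: str = "signed_mean"):
    """Overall log-fold change of a per-week trajectory.

    ``signed_mean`` returns the time-average ``(1/T) sum_t L_t`` (the
    sign-carrying ranking statistic); ``as_printed`` evaluates the literal
    form ``sign(mean) x (mean)``, i.e. the absolute mean.
    Accepts a vector (one gene) or an (n_genes, T) array.
    """
    arr = np.asarray(L, dtype=float)
    if arr.size == 0:
        raise ValueError("empty trajectory")
    mean = arr.mean(axis=-1)
    if mode == "signed_mean":
        return mean
    if mode == "as_printed":
        return np.sign(mean) * mean
    raise ValueError(f"unknown lfc mode {mode!r}")


@dataclass
class HVGList:
    """One labeled top/bottom HVG list for a genotype x condition x period."""

    label: str
    top: list
    bottom: list
    table: pd.DataFrame     # gene_id, lfc, combined_p, adjusted_p, side
    n_eligible: int

    @property
    def genes(self) -> set:
        return set(self.top) | set(self.bottom)


def select_hvgs(eligibility: pd.DataFrame, lfc: pd.Series, label: str = "",
                fraction: float = 0.05, alpha: float = 0.05) -> HVGList:
    """Label the top/bottom quantile of eligible genes as highly variable.

    Parameters
    ----------
    eligibility : DataFrame
        Indexed by gene id with columns ``combined_p`` and ``adjusted_p``.
    lfc : Series
        Genotype-specific overall log-fold change, indexed by gene id;
        must cover every eligible gene.
    fraction : float
        Quantile labeled at each end (default 5%, so top+bottom is the
        top 10% of differentially expressed genes).

    Eligible genes (adjusted p < ``alpha``) are ranked by lfc descending,
    ties broken by smaller adjusted p then lexical gene id; the first
    ``ceil(fraction * n)`` form the top list and the last the bottom list
    (truncated so no gene appears in both).
    """
    eligible = eligibility[eligibility["adjusted_p"] < alpha]
    n = len(eligible)
    if n == 0:
        log.info("list %s: 0 eligible genes", label or "<unnamed>")
        empty = pd.DataFrame(columns=["gene_id", "lfc", "combined_p", "adjusted_p", "side"])
        return HVGList(label=label, top=[], bottom=[], table=empty, n_eligible=0)
    missing = set(eligible.index) - set(lfc.index)
    if missing:
        raise ValueError(f"lfc missing for eligible genes: {sorted(missing)[:5]}")
    ranking = eligible.assign(lfc=lfc.loc[eligible.index], _gid=eligible.index)
    ranking = ranking.sort_values(["lfc", "adjusted_p", "_gid"],
                                  ascending=[False, True, True], kind="mergesort")
    k = math.ceil(fraction * n)
    top = list(ranking.index[:k])
    bottom = [g for g in ranking.index[-k:] if g not in set(top)]
    table = ranking.drop(columns="_gid").reset_index(names="gene_id")
    table["side"] = np.where(table["gene_id"].isin(top), "top",
                             np.where(table["gene_id"].isin(bottom), "bottom", ""))
    table = table[table["side"] != ""]
    return HVGList(label=label, top=top, bottom=bottom,
                   table=table[["gene_id", "lfc", "combined_p", "adjusted_p", "side"]],
                   n_eligible=n)


@dataclass
class HVGCollection:
    """The labeled lists, their merged union, and the trajectories behind them."""

    lists: list
    merged: dict                       # gene -> sorted list of source labels
    trajectories: dict = field(default_factory=dict)
    # trajectories: (condition, genotype) -> DataFrame genes x weeks of
    # full-course fitted log2 fold changes

    @property
    def merged_genes(self) -> list:
        return sorted(self.merged)

    def gene_trajectory(self, gene: str, condition: str):
        """Full-course L for one gene, averaged across genotypes, as a
        week-indexed Series (None when the condition was not fitted)."""
        frames = [df.loc[gene] for (cond, _g), df in self.trajectories.items()
                  if cond == condition and gene in df.index]
        if not frames:
            return None
        return pd.concat(frames, axis=1).mean(axis=1)

    def write_tsv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        for lst in self.lists:
            t = lst.table.copy()
            t.insert(1, "list_label", lst.label)
            t.to_csv(outdir / f"hvg_{lst.label.replace('.', '_')}.tsv",
                     sep="\t", index=False)
        merged = pd.DataFrame(
            {"gene_id": self.merged_genes,
             "source_lists": [";".join(self.merged[g]) for g in self.merged_genes]})
        merged.to_csv(outdir / "hvg_merged.tsv", sep="\t", index=False)
        (outdir / "hvg_merged_genes.txt").write_text(
            "".join(f"{g}\n" for g in self.merged_genes))


def build_and_merge_lists(de_results: dict, fraction: float = 0.05,
                          alpha: float = 0.05,
                          lfc_mode: str = "signed_mean") -> HVGCollection:
    """Build the eight labeled HVG lists and merge them.

    Parameters
    ----------
    de_results : dict
        ``(condition, window, genotype) -> DEResult`` as produced by
        :func:`wallwise.timecourse.run_contrasts`; ``window`` is one of
        ``"full"``, ``"drought"``, ``"recovery"``.

    For every (condition, window) the genotypes' raw p-values are
    Fisher-combined, BH-adjusted across genes, and one list per genotype
    is selected by the genotype-specific lfc.  With two genotypes, two
    drought conditions and the two pre-flowering sub-periods this yields
    eight lists; their union (with source tags) is the merged HVG set.
    """
    groups: dict = {}
    for (condition, window, genotype), res in de_results.items():
        groups.setdefault((condition, window), {})[genotype] = res

    lists = []
    merged: dict = {}
    trajectories = {}
    for (condition, window), per_geno in sorted(groups.items()):
        genotypes = sorted(per_geno)
        pmat = pd.DataFrame({g: per_geno[g].table.set_index("gene_id")["p"]
                             for g in genotypes})
        valid = pmat.dropna()
        n_na = len(pmat) - len(valid)
        if n_na:
            log.info("%s.%s: %d genes with NA fits excluded", condition, window, n_na)
        if valid.empty:
            for g in genotypes:
                lists.append(HVGList(label=f"{condition}.{window}.{g}", top=[], bottom=[],
                                     table=pd.DataFrame(), n_eligible=0))
            continue
        x2, comb = fisher_combine(valid.to_numpy())
        adj = bh_adjust(comb)
        elig = pd.DataFrame({"combined_p": comb, "adjusted_p": adj}, index=valid.index)
        for g in genotypes:
            L = per_geno[g].L
            if (condition, g) not in trajectories and window == "full":
                trajectories[(condition, g)] = L
            lfc = pd.Series(overall_lfc(L.to_numpy(), mode=lfc_mode), index=L.index)
            lst = select_hvgs(elig, lfc, label=f"{condition}.{window}.{g}",
                              fraction=fraction, alpha=alpha)
            lists.append(lst)
            for gene in lst.genes:
                merged.setdefault(gene, []).append(lst.label)
    for gene in merged:
        merged[gene] = sorted(merged[gene])
    return HVGCollection(lists=lists, merged=merged, trajectories=trajectories)
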