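"""Core in-memory containers: the counts experiment and its normalized form.

Both are thin wrappers over :class:`pandas.DataFrame` objects with the
row/column contracts validated at construction, plus TSV round-trip I/O
(genes as rows, samples as columns; a sidecar design table keyed by
sample id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("genotype", "tissue", "condition", "week", "replicate")


@dataclass
class CountsExperiment:
    """Gene x sample integer count matrix plus per-sample design metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Nonnegative integers, index = gene ids, columns = sample ids.
    design : pandas.DataFrame
        Indexed by sample id with columns ``genotype, tissue, condition,
        week, replicate``; every count column must appear in the design.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        # align design rows to count columns
        self.design = self.design.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def write_tsv(self, counts_path, design_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.design.to_csv(design_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, counts_path, design_path) -> "CountsExperiment":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        return cls(counts=counts, design=design)


@dataclass
class NormalizedMatrix:
    """Upper-quartile-normalized expression values.

    ``values`` are counts divided by the per-sample size factor;
    ``log2`` is ``log2(values + pseudocount)``.  Size factors are rescaled
    to geometric mean 1 so normalized values stay on the counts scale.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    design: pd.DataFrame
    pseudocount: float = 1.0
    log2: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if list(self.values.columns) != list(self.size_factors.index):
            raise ValueError("size factor index must match sample columns")
        self.design = self.design.loc[self.values.columns]
        self.log2 = np.log2(self.values + self.pseudocount)

    def write_tsv(self, values_path, factors_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        if factors_path is not None:
            self.size_factors.rename("size_factor").to_csv(
                factors_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, values_path, factors_path, design_path,
                 pseudocount: float = 1.0) -> "NormalizedMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        factors = pd.read_csv(factors_path, sep="\t", index_col="sample_id")["size_factor"]
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        return cls(values=values, size_factors=factors.loc[values.columns],
                   design=design, pseudocount=pseudocount)
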