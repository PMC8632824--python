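"""Low-expression filtering and upper-quartile normalization."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountsExperiment, NormalizedMatrix

log = logging.getLogger(__name__)


def filter_low_expressed(experiment: CountsExperiment,
                         min_mean: float = 1.0) -> CountsExperiment:
    """Drop genes whose mean count across all samples falls below ``min_mean``.

    Gene order is preserved.  An empty result is allowed (warned, not an
    error) so that aggressive thresholds fail loudly downstream instead.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be nonnegative")
    keep = experiment.counts.mean(axis=1) >= min_mean
    if not keep.any():
        log.warning("low-expression filter removed every gene (min_mean=%g)", min_mean)
    return CountsExperiment(counts=experiment.counts.loc[keep],
                            design=experiment.design)


def upper_quartile_normalize(experiment: CountsExperiment,
                             pseudocount: float = 1.0) -> NormalizedMatrix:
    """Between-sample upper-quartile normalization.

    Each sample's factor is the 75th percentile of its *nonzero* counts
    (linear interpolation), rescaled so the factors have geometric mean 1;
    normalized values are counts divided by the factor, keeping the matrix
    on the counts scale.  The log2 matrix uses ``log2(value + pseudocount)``.
    """
    counts = experiment.counts
    factors = np.empty(counts.shape[1])
    for j, sample in enumerate(counts.columns):
        col = counts[sample].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        factors[j] = np.percentile(nonzero, 75)
    factors = factors / np.exp(np.mean(np.log(factors)))
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    values = counts / sf
    return NormalizedMatrix(values=values, size_factors=sf,
                            design=experiment.design, pseudocount=pseudocount)
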