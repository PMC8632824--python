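"""Shared fixtures: seeded simulated datasets reused across test modules.

Session scope keeps the heavier simulations (the 2000-gene null and the
default-design recovery run) to a single execution each.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import wallwise as w
from wallwise.config import SimulationConfig


def make_experiment(counts, n_weeks=None, genotype="RTx430", condition="control",
                    tissue="leaf"):
    """Wrap a raw gene x sample array as a CountsExperiment with a minimal
    one-genotype design (samples become consecutive weeks, one replicate)."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    design = pd.DataFrame({
        "genotype": genotype, "tissue": tissue, "condition": condition,
        "week": (np.arange(n_samples) % (n_weeks or n_samples)) + 1,
        "replicate": 1,
    }, index=pd.Index(sample_ids, name="sample_id"))
    frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                         columns=sample_ids)
    return w.CountsExperiment(counts=frame, design=design)


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(SimulationConfig(), n_genes=200, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    experiment, truth = w.simulate_experiment(small_config)
    annotations = w.simulate_go_annotations(experiment.gene_ids, small_config, truth)
    return experiment, truth, annotations


@pytest.fixture(scope="session")
def null_de():
    """Null experiment (no planted effects): DE results of every contrast."""
    cfg = SimulationConfig(n_genes=2000, frac_responsive=0.0, seed=7)
    experiment, truth = w.simulate_experiment(cfg)
    norm = w.upper_quartile_normalize(w.filter_low_expressed(experiment, 1.0))
    results = w.run_contrasts(norm)
    return cfg, truth, results


@pytest.fixture(scope="session")
def recovery_run():
    """Default study design with planted responses, analyzed end to end."""
    cfg = SimulationConfig(seed=1)
    experiment, truth = w.simulate_experiment(cfg)
    annotations = w.simulate_go_annotations(experiment.gene_ids, cfg, truth)
    norm = w.upper_quartile_normalize(w.filter_low_expressed(experiment, 1.0))
    results = w.run_contrasts(norm)
    collection = w.build_and_merge_lists(results)
    return {"config": cfg, "experiment": experiment, "truth": truth,
            "annotations": annotations, "norm": norm, "results": results,
            "collection": collection}
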