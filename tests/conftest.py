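"""Shared fixtures: synthetic cohorts at the default study conditions and a
small fast variant for unit tests. Session scope keeps the expensive default
cohort and its derivation to a single computation."""

import numpy as np
import pytest

from senset import gene_sets, pipeline, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (seed 1) with truth and prior lists."""
    cfg = synthetic.CohortConfig(seed=1)
    adata, truth = synthetic.generate_cohort(cfg)
    lists = synthetic.generate_prior_lists(cfg, truth)
    return cfg, adata, truth, lists


@pytest.fixture(scope="session")
def default_derivation(default_cohort):
    """Full signature derivation on the default cohort."""
    cfg, adata, truth, lists = default_cohort
    res = pipeline.derive_signature(adata, lists, seed=1)
    return res


def small_config(seed=0, **overrides):
    """A scaled-down cohort for fast unit tests (not the study conditions)."""
    kwargs = dict(
        n_cell_types=3,
        cells_per_type_per_group=300,
        n_genes=400,
        n_true_markers=25,
        aging_shift_genes=40,
        prior_list_specs=tuple(
            synthetic.PriorListSpec(name=f"prior_{c}", n_genes=60, marker_recall=0.6)
            for c in "ABC"),
        seed=seed,
    )
    kwargs.update(overrides)
    return synthetic.CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config(seed=11)
    adata, truth = synthetic.generate_cohort(cfg)
    lists = synthetic.generate_prior_lists(cfg, truth)
    return cfg, adata, truth, lists


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
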