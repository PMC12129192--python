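"""Shared fixtures: small synthetic cohorts and derived feature blocks.

Expensive artifacts (feature derivations over several seeds) are
session-scoped so the integration-level tests can share them.
"""

import numpy as np
import pytest

import adgcn_omics as ao
from adgcn_omics.pipeline import derive_feature_blocks

N_SEEDS = 5


@pytest.fixture(scope="session")
def small_cohort():
    """A default-parameter cohort small enough for unit tests."""
    return ao.generate_cohort(ao.CohortConfig(n_samples=200, seed=11))


@pytest.fixture(scope="session")
def derivations():
    """Feature derivations for the integration/ablation comparisons.

    One full cohort per seed (discovery/target split inside), shared by the
    ensemble-ladder, graph-ablation and graph-vs-ensemble tests.
    """
    out = []
    for seed in range(N_SEEDS):
        cfg = ao.CohortConfig(n_samples=500, n_snps=200, n_ld_blocks=20,
                              seed=seed)
        cohort = ao.generate_cohort(cfg)
        out.append(derive_feature_blocks(cohort, seed=seed))
    return out


def gcn_features(fd):
    return np.hstack([fd.blocks.clinical_bdi, fd.blocks.prs,
                      fd.blocks.methylation_top])
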