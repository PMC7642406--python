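from __future__ import annotations

import pytest

from viteseq import simulate


@pytest.fixture(scope="session")
def cohort() -> simulate.SyntheticCohort:
    """Default-size synthetic cohort shared across the suite (~10k variants
    per individual, 8 planted editing events, 60 control sites)."""
    return simulate.simulate_cohort(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def genome_genes(cohort):
    return cohort.genome, cohort.genes


@pytest.fixture(scope="session")
def editing_cohort() -> simulate.SyntheticCohort:
    """Cohort sized for editing recovery: ≥ 200 pileup sites, clean edits."""
    cfg = simulate.SimulationConfig(
        seed=23,
        snp_rate=0.002,
        indel_rate=0.0004,
        n_auto_editing_events=48,
        n_control_sites=160,
    )
    return simulate.simulate_cohort(cfg)
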