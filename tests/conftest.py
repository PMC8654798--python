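import numpy as np
import pandas as pd
import pytest

from poemod.scan import TrioSpec
from poemod.synthio import (
    ModifierSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_methylation,
)


def make_cohort(seed=0, n_families=400, interaction_beta=0.4, **overrides):
    """Small standard cohort: one parental-pattern CpG with a continuous
    modifier interaction, one bipolar CpG, one non-POE CpG."""
    kwargs = dict(
        n_families=n_families,
        trio_fraction=0.7,
        n_snps=2,
        maf_range=(0.2, 0.4),
        n_cpgs=3,
        poe_patterns=["parental", "bipolar_dominance", "none"],
        beta_add=0.3,
        beta_poe=0.5,
        modifiers=[
            ModifierSpec(
                name="mod",
                kind="continuous",
                main_beta=0.2,
                add_interaction_beta=0.1,
                interaction_beta=interaction_beta,
                target_cpg=0,
            )
        ],
        noise_sd=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    return simulate_methylation(simulate_cohort(cfg), cfg), cfg


@pytest.fixture(scope="session")
def cohort():
    data, _ = make_cohort()
    return data


@pytest.fixture(scope="session")
def trio():
    return TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="mod")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
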