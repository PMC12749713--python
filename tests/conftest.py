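import numpy as np
import pytest

from chronomodes import GeneratorConfig, generate_cohort

#: small phenome keeps fixture generation fast; family structure preserved
SMALL_PHENOME = {"behavior": 40, "diagnosis": 25, "medication": 12}


def small_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_participants=400,
        n_phenotypes_per_family=dict(SMALL_PHENOME),
        seed=123,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def planted_config(seed: int = 1, n: int = 2000, **overrides) -> GeneratorConfig:
    """One planted mode at latent-target correlation 0.3 (the study's desk scale)."""
    base = dict(
        n_participants=n,
        n_modes=1,
        mode_strengths=(0.3,),
        age_effects=(-0.3,),
        phenotype_effects=(0.3,),
        n_phenotypes_per_family={"behavior": 5, "diagnosis": 5, "medication": 5},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def planted_cohort():
    """n=2000 cohort with a single mode at strength 0.3, plus its truth."""
    return generate_cohort(planted_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
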