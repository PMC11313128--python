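import warnings

import pytest

from clusterpa.simulate import SimulationConfig, generate_population


@pytest.fixture(scope="session")
def single_wave():
    """One study, 100 schools x 25 pupils, one wave: the cross-sectional
    setting where the random-intercept ICC equals the generating ICC."""
    cfg = SimulationConfig(
        n_studies=1, schools_per_study=100, pupils_per_school=25,
        waves=(0.0,), seed=101,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = generate_population(cfg)
    return data, cfg


@pytest.fixture(scope="session")
def two_wave_clean():
    """One study, 300 schools x 25 pupils, two waves, complete data and
    no gender effect: correlation oracles hold in their simplest form."""
    cfg = SimulationConfig(
        n_studies=1, schools_per_study=300, pupils_per_school=25,
        waves=(0.0, 1.0), baseline_year_probs={4: 1.0},
        missing_rate=0.0, min_valid_days_distribution={5: 1.0},
        gender_effect=0.0, seed=7,
    )
    return generate_population(cfg), cfg
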