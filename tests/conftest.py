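import dataclasses

import pytest

from pzqma import simulate


def _noiseless_config(**overrides) -> simulate.SimulationConfig:
    """Default study design with all randomness stripped: no assay noise,
    no between-subject variability, no outlier, censoring disabled."""
    base = simulate.SimulationConfig(
        assay_cv=0.0,
        dbs_extra_cv=0.0,
        outlier_fraction=0.0,
        lloq_ug_ml={a: 0.0 for a in simulate.ANALYTES},
    )
    models = {a: dataclasses.replace(m, bsv_cv=0.0)
              for a, m in base.analyte_models.items()}
    return dataclasses.replace(base, analyte_models=models, **overrides)


@pytest.fixture(scope="session")
def noiseless_config():
    return _noiseless_config()


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    """Deterministic 9-subject cohort: observed = model exactly."""
    return simulate.generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def unit_ratio_cohort():
    """Noiseless cohort with blood:plasma ratio forced to 1 for every
    analyte, so all three matrices carry identical concentrations."""
    base = _noiseless_config()
    models = {a: dataclasses.replace(m, r_blood_plasma=1.0)
              for a, m in base.analyte_models.items()}
    cfg = dataclasses.replace(base, analyte_models=models)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default (noisy, censored) study design."""
    return simulate.generate_cohort(simulate.SimulationConfig(rng_seed=7))


@pytest.fixture
def noiseless_config_factory():
    return _noiseless_config
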