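import numpy as np
import pytest

import hydrotime as ht


@pytest.fixture(scope="session")
def table2():
    return ht.load_fixture("table2")


@pytest.fixture(scope="session")
def table2_params(table2):
    """Published parameter triples keyed by population label."""
    return {pop: ht.fixture_params(pop) for pop in table2.index}


@pytest.fixture(scope="session")
def pb_params():
    return ht.HydrotimeParams(theta_H=13.63, psi_b50=-2.69, sigma_psib=0.58)


def exact_timecourses(params, psi_levels, days, population="pop", replicate=1,
                      n_viable=10**6):
    """Noise-free 'expected count' curves from the model (counts rounded to
    1 in n_viable, so fractions are exact to 1e-6)."""
    out = []
    for psi in psi_levels:
        frac = ht.predict_cumulative_fraction(params, psi, days)
        out.append(
            ht.TimeCourse(
                population=population,
                replicate=replicate,
                psi=psi,
                days=days,
                cum_germinated=np.round(frac * n_viable),
                n_viable=n_viable,
            )
        )
    return out


@pytest.fixture(scope="session")
def small_experiment(pb_params):
    """One small simulated experiment used across fitting tests."""
    design = ht.ExperimentDesign(rng_seed=20240915)
    return ht.simulate_experiment(pb_params, design, "PB"), design
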