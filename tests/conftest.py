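import numpy as np
import pytest

import dcepref as d
from dcepref.studydata import study_population


@pytest.fixture(scope="session")
def scheme():
    return d.study_scheme()


@pytest.fixture(scope="session")
def design():
    return d.study_design()


@pytest.fixture(scope="session")
def population():
    return study_population()


@pytest.fixture(scope="session")
def study_dataset(design, population):
    """One synthetic study-scale dataset: 103 respondents on the shipped design."""
    respondents = d.draw_respondents(103, seed=11)
    coefs = d.draw_individual_coefficients(population, 103, seed=12)
    return d.simulate_choices(design, coefs, respondents, seed=13)


def simulate_study(n, seed, population=None, design=None, shift=None):
    """Simulate n respondents under the study data-generating process.

    ``shift`` = (covariate, category, {column: delta}) induces a subgroup
    preference difference before choices are drawn.
    """
    population = population or study_population()
    design = design or d.study_design()
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    respondents = d.draw_respondents(n, seed=s1)
    coefs = d.draw_individual_coefficients(population, n, seed=s2)
    if shift is not None:
        cov, cat, deltas = shift
        coefs = d.shift_preferences(coefs, respondents, cov, cat, deltas)
    return d.simulate_choices(design, coefs, respondents, seed=s3)
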