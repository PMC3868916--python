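import pytest

from prioritytag import (
    GenerativeParams,
    SearchCondition,
    build_design,
    generate_trials,
)


def design_conditions(design):
    """All (x, target type) cells of a design as SearchConditions."""
    return [SearchCondition(design.n, cell.x, cell.t) for cell in design.cells]


@pytest.fixture(scope="session")
def exp1_design():
    return build_design("exp1")


@pytest.fixture(scope="session")
def noiseless_params():
    """Deterministic generative process: no trial noise, no lapses, no
    outliers, no individual differences."""
    return GenerativeParams(
        a=30.0, b=-70.0, d=760.0, c_true=1,
        sigma=0.0, lapse=0.0, outlier_rate=0.0,
        a_sd=0.0, b_sd=0.0, d_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_trials_exp1(exp1_design, noiseless_params):
    return generate_trials(exp1_design, noiseless_params, n_participants=3, seed=11)


@pytest.fixture(scope="session")
def noisy_trials_exp1(exp1_design):
    """22 participants at the default study-scale generative parameters."""
    return generate_trials(exp1_design, GenerativeParams(), n_participants=22, seed=7)
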