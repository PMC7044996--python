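import warnings

import pandas as pd
import pytest

import gprisk

# statsmodels emits convergence chatter on tiny CV folds; tests assert on
# results, not warnings
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_study() -> gprisk.SyntheticStudy:
    """A compact two-wave study for structural tests (fast to generate)."""
    cfg = gprisk.SyntheticConfig(n_practices=150, gpps_respondents_per_practice=40,
                                 seed=11)
    return gprisk.generate_panel(cfg)


@pytest.fixture(scope="session")
def truth_study() -> gprisk.SyntheticStudy:
    """A larger study without survey respondents, for truth-level model tests."""
    cfg = gprisk.SyntheticConfig(n_practices=3000,
                                 gpps_respondents_per_practice=0, seed=23)
    return gprisk.generate_panel(cfg)


@pytest.fixture(scope="session")
def develop_report(small_study):
    """One shared development run (the case-mix fits are the slow step)."""
    return gprisk.run_develop(small_study, seed=11)


@pytest.fixture
def toy_roster() -> pd.DataFrame:
    return pd.DataFrame({
        "practice_id": ["P1", "P1", "P2"],
        "gp_id": ["g1", "g2", "g3"],
        "age": [40.0, 58.0, 35.0],
        "gender": ["F", "M", "F"],
        "fte": [1.0, 0.5, 0.8],
        "role": ["partner", "partner", "salaried"],
    })
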