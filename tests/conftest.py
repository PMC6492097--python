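import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_survival():
    """Deterministic 10-subject survival data with 6 events, no ties."""
    time = np.array([0.8, 1.4, 0.3, 2.2, 1.1, 0.6, 1.9, 0.9, 1.6, 0.45])
    event = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 0])
    x = np.array([21.0, 24.5, 27.0, 22.3, 29.1, 25.5, 23.7, 26.4, 20.6, 28.2])
    return time, event, x


@pytest.fixture
def proportional_fits(rng):
    """StudyFits whose covariances are proportional: S_i = lambda_i * S."""
    from fpmeta import FPSpec, StudyFit

    spec = FPSpec((1.0, 2.0))
    A = rng.normal(size=(2, 2))
    S = A @ A.T + 0.5 * np.eye(2)
    lams = [1.0, 4.0, 2.5]
    return [
        StudyFit(
            study_id=f"s{i}", spec=spec, beta=rng.normal(size=2),
            cov=lam * S, gamma=np.zeros(0), loglik=-100.0, n_events=50,
        )
        for i, lam in enumerate(lams)
    ]


@pytest.fixture(scope="session")
def small_cohorts():
    """A small consortium-like dataset reused across pooling tests."""
    from fpmeta import make_erfc_like

    studies, sigma = make_erfc_like(
        n_cohorts=6, mean_size=2500, size_sigma=0.4, seed=42
    )
    return studies, sigma


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohorts):
    from fpmeta import FPSpec, fit_cox_fp

    studies, _ = small_cohorts
    return [fit_cox_fp(s, FPSpec((1.0, 2.0))) for s in studies]
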