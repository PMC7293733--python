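import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fgfr_atlas as fa

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix():
    """2 genes x 3 samples, values at 6 significant digits."""
    return fa.ExpressionMatrix(
        pd.DataFrame(
            [[1234.56, 0.0, 42.0], [7.5, 300.001, 99999.9]],
            index=["FGFR1", "FGFR3"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def tiny_annotations():
    return fa.SampleAnnotations(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "cohort": ["BLCA", "BLCA", "CHOL"],
                "tissue": ["tumor", "normal", "tumor"],
                "pair_id": ["p1", "p1", pd.NA],
                "os_days": [100.0, pd.NA, 400.0],
                "os_event": ["event", pd.NA, "censored"],
            }
        )
    )


@pytest.fixture
def small_cohort():
    """A BLCA-like cohort with a planted adverse survival link on FGFR1."""
    spec = fa.CohortSpec(
        cohort="BLCA",
        n_tumor=80,
        n_normal=20,
        survival_link=fa.SurvivalLink("FGFR1", 0.8),
        matched_fraction=0.5,
        seed=9,
    )
    return fa.generate_cohort(spec)


def make_records(rng, n, hazard=0.01, censor=0.003, cov_sd=1.0):
    """Ad-hoc survival records with an uninformative covariate."""
    t_event = rng.exponential(1 / hazard, n)
    t_cens = rng.exponential(1 / censor, n)
    return [
        fa.SurvivalRecord(
            sample_id=f"r{i}",
            time=float(max(min(te, tc), 1e-3)),
            event=bool(te <= tc),
            covariate=float(rng.normal(0, cov_sd)),
        )
        for i, (te, tc) in enumerate(zip(t_event, t_cens))
    ]


@pytest.fixture
def record_factory():
    return make_records
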