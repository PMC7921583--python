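import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mastphen import run_all, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mastphen.simulate import SimulationConfig


def records(rows):
    """Build a capture-record frame from (date, species, age, fledgling, sex,
    ...) tuples with sensible defaults for the unstated fields."""
    base = {
        "mass_g": 12.5,
        "wing_mm": 72,
        "brood_patch": np.nan,
        "time_min": 600,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {
            "session_date": pd.Timestamp(row[0]),
            "species": row[1],
            "ring_id": row[2] if len(row) > 2 and isinstance(row[2], str) else f"X{i:04d}",
            "euring_age": row[3] if len(row) > 3 else 4,
            "fledgling": row[4] if len(row) > 4 else 0,
            "sex": row[5] if len(row) > 5 else "U",
            **base,
        }
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests."""
    return simulate_study(SimulationConfig(), seed=20240)


@pytest.fixture(scope="session")
def default_bundle(default_study):
    """Full pipeline output on the shared synthetic study."""
    study = default_study
    rain = study.rainfall.set_index("date")["rain_mm"]
    scores = study.cone_scores.rename(
        columns={"autumn_year": "cone_year", "score": "cone_score"}
    )
    return run_all(study.captures, rain, scores, study.isotopes, study.cone_samples)
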