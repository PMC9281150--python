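import numpy as np
import pandas as pd
import pytest

from pensiongap.cohort import PIThresholds
from pensiongap.model import MortalityGradientModel
from pensiongap.simulate import SimulationConfig
from pensiongap.tabulate import PeriodDef


@pytest.fixture(scope="session")
def thresholds2018() -> PIThresholds:
    """Legal minimum/maximum monthly benefits in force in 2018 (EUR/month)."""
    return PIThresholds(657.60, 2617.53, year=2018)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Defect-free four-group registry of moderate size."""
    return SimulationConfig(n_records=30_000, seed=11, contamination_rates={})


@pytest.fixture(scope="session")
def fitted_results(clean_config):
    """Full pipeline fit on the clean registry (shared; treat as read-only)."""
    return MortalityGradientModel.from_simulation(clean_config).fit()


@pytest.fixture
def single_period() -> PeriodDef:
    return PeriodDef.from_years("P", 2005, 2018)


def as_record_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a record frame with parsed dates from plain dicts."""
    df = pd.DataFrame(rows)
    for col in ("birth_date", "pension_start_date", "pension_end_date", "death_date"):
        if col in df:
            df[col] = pd.to_datetime(df[col], errors="coerce")
        else:
            df[col] = pd.NaT
    return df


def base_record(**overrides) -> dict:
    rec = dict(
        person_id="X",
        sex="male",
        birth_date="1940-03-15",
        pension_start_date="2005-03-15",
        pension_end_date="",
        death_date="",
        benefit_type="retirement",
        regime="general",
        retirement_age_years=65.0,
        initial_pension_eur_month=900.0,
    )
    rec.update(overrides)
    return rec
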