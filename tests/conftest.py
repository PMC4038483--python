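import warnings

import numpy as np
import pandas as pd
import pytest

from pondshift import refdata
from pondshift.synthetic_data import scenario_chorus_frog

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def occupancy_series() -> pd.Series:
    return refdata.CHORUS_FROG_OCCUPANCY.copy()


@pytest.fixture(scope="session")
def ln_density_series() -> pd.Series:
    return refdata.CHORUS_FROG_LN_DENSITY.copy()


@pytest.fixture(scope="session")
def scenario_bundle():
    """Canned drought scenario at the canonical seed (shared, read-only)."""
    return scenario_chorus_frog(0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def occupancy_of(bundle, species="PTR") -> pd.Series:
    sv = bundle["survey"]
    f = sv[(sv.species_id == species) & sv.present]
    years = sorted(sv.year.unique())
    return (f.groupby("year").pond_id.nunique()
            .reindex(years).fillna(0).astype(float))


def mean_density_of(bundle, species="PTR") -> pd.Series:
    sv = bundle["survey"]
    f = sv[(sv.species_id == species) & sv.present]
    years = sorted(sv.year.unique())
    return f.groupby("year").density.mean().reindex(years)
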