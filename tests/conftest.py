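import numpy as np
import pandas as pd
import pytest

from alien_accrual import records_pipeline as rp
from alien_accrual import synth_data as sd


def make_db(rows):
    """Build a RecordDatabase from (species, region, continent, taxon,
    year_raw, status, source, priority) tuples."""
    df = pd.DataFrame(rows, columns=rp.RECORD_COLUMNS)
    return rp.RecordDatabase(df)


@pytest.fixture
def messy_db():
    """Hand-built database exercising ranges, duplicates and casuals."""
    return make_db(
        [
            ("sp1", "rA", "EU", "plants", "1873", "established", "s1", 1),
            ("sp1", "rA", "EU", "plants", "1900", "established", "s2", 2),
            ("sp1", "rB", "EU", "plants", "1850", "established", "s1", 1),
            ("sp2", "rA", "EU", "plants", "<1980", "established", "s1", 1),
            ("sp2", "rC", "NA", "plants", "1940-1949", "established", "s1", 1),
            ("sp3", "rA", "EU", "insects", "1800-1850", "established", "s1", 1),
            ("sp4", "rB", "EU", "insects", "1499", "established", "s1", 1),
            ("sp5", "rC", "NA", "insects", "2003", "casual", "s1", 1),
            ("sp6", "rC", "NA", "insects", "1995", "established", "s1", 1),
        ]
    )


@pytest.fixture
def synth_config():
    return sd.SynthConfig(
        taxa=[
            sd.TaxonSpec("plants", "sigmoidal", (120.0, 8.0, 360.0), 800),
            sd.TaxonSpec("insects", "exponential", (0.05, 0.016), 800),
        ],
        regions=[(f"r{i}", f"c{i % 3}") for i in range(12)],
        frac_ranged=0.2,
        frac_casual=0.1,
        frac_duplicate=0.3,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
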