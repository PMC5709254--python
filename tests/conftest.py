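import pandas as pd
import pytest

from pedtrauma.barell import annotate_tbi
from pedtrauma.cohort import extract_cohort
from pedtrauma.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def records(default_config) -> pd.DataFrame:
    """Medium synthetic visit table (~10k visits) shared across tests."""
    return generate(default_config)


@pytest.fixture(scope="session")
def cohort(records) -> pd.DataFrame:
    """Extracted cohort with Barell/TBI annotations."""
    return annotate_tbi(extract_cohort(records))


def make_cohort_frame(rows):
    """Build a minimal annotated cohort table from dict-like rows.

    Fills the design columns (unit weight, one cluster per row, one stratum)
    unless the row overrides them.
    """
    defaults = dict(weight=1.0, stratum_id=0, died=0, tbi_primary=0,
                    mechanism="bicyclist", age=10, female=0, trauma_level12=0,
                    year=2006)
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, cluster_id=i)
        r.update(row)
        out.append(r)
    return pd.DataFrame(out)
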