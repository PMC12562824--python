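import warnings

import numpy as np
import pandas as pd
import pytest

import ocumarker as om
from ocumarker.cohort import CONTROL, GLAUCOMA


@pytest.fixture(scope="session")
def clean_cohort():
    """Default-shaped cohort with corruption disabled (no outliers/missing)."""
    cfg = om.default_config(seed=11, outlier_rate=0.0, missing_rate=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = om.generate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-shaped cohort with mild contamination and missingness."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = om.generate_cohort(om.default_config(seed=7))
    return table, truth


def small_table(values_by_column, scales=None, compartments=None,
                n_control=5):
    """Build a minimal CohortTable from raw column vectors."""
    scales = scales or {}
    compartments = compartments or {}
    data = pd.DataFrame(values_by_column)
    n = len(data)
    data.index = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    data.insert(0, "group", [CONTROL] * n_control + [GLAUCOMA] * (n - n_control))
    meta = {c: om.VariableMeta(scale=scales.get(c, "continuous"),
                               compartment=compartments.get(c))
            for c in values_by_column}
    return om.CohortTable(data, meta)
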