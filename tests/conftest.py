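import numpy as np
import pandas as pd
import pytest

from jaderpv import (clean_bmi, default_study_config, deduplicate,
                     filter_suspected, generate, merge_cases)


def make_cases(rows):
    """Build a minimal merged case table from (drugs, events) tuples."""
    n = len(rows)
    return pd.DataFrame({
        "case_id": [f"C{i}" for i in range(n)],
        "sex": ["female"] * n,
        "age_years": [60.0] * n,
        "height_cm": [160.0] * n,
        "weight_kg": [55.0] * n,
        "bmi": [21.5] * n,
        "suspected_drugs": [frozenset(d) for d, _ in rows],
        "events": [frozenset(e) for _, e in rows],
    })


def cases_from_tables(drug, reac, demo):
    """Standard cleaning path: suspected filter, dedup, merge, BMI clean."""
    d = deduplicate(filter_suspected(drug), "DRUG")
    r = deduplicate(reac, "REAC")
    cases, _ = clean_bmi(merge_cases(d, r, demo))
    return cases


@pytest.fixture(scope="session")
def study_tables():
    """One study-scale synthetic database shared across tests."""
    cfg = default_study_config(n_cases=30_000, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def study_cases(study_tables):
    drug, reac, demo, _ = study_tables
    return cases_from_tables(drug, reac, demo)


def fisher_enumeration(a, b, c, d):
    """Independent two-sided Fisher oracle: exhaustive hypergeometric sum.

    Fixes the margins and sums P(table) over all tables whose point
    probability does not exceed the observed table's.
    """
    from scipy.stats import hypergeom
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-10)].sum()))
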