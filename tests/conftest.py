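import logging

import numpy as np
import pandas as pd
import pytest

from protnet.group_stats import ClinicalTable
from protnet.preprocess import ExpressionMatrix

logging.getLogger("protnet").setLevel(logging.ERROR)


@pytest.fixture
def raw_matrix():
    """Small raw intensity matrix with missing values."""
    rng = np.random.default_rng(7)
    vals = 2.0 ** rng.uniform(18, 25, size=(8, 10))
    df = pd.DataFrame(
        vals,
        index=[f"PROT{i}" for i in range(8)],
        columns=[f"S{j:02d}" for j in range(10)],
    )
    df.iloc[0, :3] = np.nan
    df.iloc[3, 5:] = np.nan
    return ExpressionMatrix(df, stage="raw")


@pytest.fixture
def zscored_matrix():
    rng = np.random.default_rng(11)
    vals = rng.standard_normal((6, 20))
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    df = pd.DataFrame(
        vals,
        index=[f"PROT{i}" for i in range(6)],
        columns=[f"S{j:02d}" for j in range(20)],
    )
    return ExpressionMatrix(df, stage="zscored")


def make_survival_data(n=80, log_hr=0.0, seed=0, censor_scale=10.0):
    """Exponential survival tied to a standard-normal covariate."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    lam = 0.1 * np.exp(log_hr * x)
    T = rng.exponential(1.0 / lam)
    C = rng.exponential(censor_scale, n)
    times = np.minimum(T, C)
    events = T <= C
    return times, events, x


def make_clinical(times, events, subtypes=None) -> ClinicalTable:
    n = len(times)
    ids = [f"S{i:03d}" for i in range(n)]
    if subtypes is None:
        subtypes = ["ER-true"] * n
    return ClinicalTable(
        pd.DataFrame(
            {"subtype": subtypes, "time": times, "event": events}, index=ids
        )
    )
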