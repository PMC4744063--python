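"""Shared fixtures: small survey datasets built programmatically."""

import numpy as np
import pandas as pd
import pytest

from surveysel import SurveyDataset, VariableMeta


def make_dataset(X, y, weights=None, strata=None, psus=None, names=None,
                 binary_cols=()):
    """Assemble a SurveyDataset from arrays (NaN = missing in X)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names if names is not None else [f"x{j + 1}" for j in range(p)]
    values = pd.DataFrame(X, columns=names)
    values["y"] = np.asarray(y, dtype=float)
    meta = [VariableMeta(nm, "binary" if nm in binary_cols else "continuous", "predictor")
            for nm in names]
    meta.append(VariableMeta("y", "binary", "outcome"))
    if weights is not None:
        values["w"] = weights
        meta.append(VariableMeta("w", "continuous", "weight"))
    if strata is not None:
        values["strat"] = strata
        meta.append(VariableMeta("strat", "continuous", "stratum"))
    if psus is not None:
        values["psu"] = psus
        meta.append(VariableMeta("psu", "continuous", "psu"))
    return SurveyDataset(values, meta)


@pytest.fixture
def toy_dataset():
    """10 records, 5 predictors, one missing cell, no design columns."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((10, 5))
    X[3, 2] = np.nan
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
    return make_dataset(X, y)


@pytest.fixture
def survey_dataset():
    """600 records under a 10-stratum, 2-PSU design with unequal weights."""
    rng = np.random.default_rng(7)
    n = 600
    X = rng.standard_normal((n, 3))
    eta = -1.0 + 0.8 * X[:, 0] + 0.4 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    strata = np.repeat(np.arange(10), 60)
    psus = rng.integers(0, 2, size=n)
    weights = rng.lognormal(0, 0.4, size=n)
    return make_dataset(X, y, weights=weights, strata=strata, psus=psus)
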