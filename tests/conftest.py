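import numpy as np
import pandas as pd
import pytest

import beeftradeoff as bt


@pytest.fixture(scope="session")
def default_herd():
    return bt.generate_herd(bt.default_config(seed=1))


@pytest.fixture(scope="session")
def indicators(default_herd):
    table, _sols = bt.pretreat_herd(default_herd)
    return table


class LinearStub:
    """Minimal model object: linear function of named predictors."""

    def __init__(self, predictors, coefs, intercept=0.0, response="y"):
        self.predictors = list(predictors)
        self.coefs = np.asarray(coefs, float)
        self.intercept = intercept
        self.response = response
        self.family = "stub"

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.predictors].to_numpy()
        return self.intercept + np.asarray(X, float) @ self.coefs

    def predict_full(self, df):
        return self.predict(df[self.predictors].to_numpy())


@pytest.fixture
def linear_stub():
    return LinearStub
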