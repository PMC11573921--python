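import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles module importable

from faim.data import Dataset, DesignMatrix, Schema, from_dataframe


@pytest.fixture
def toy_schema():
    return Schema(
        outcome="y",
        sensitive=("race", "sex"),
        predictors=("age", "score"),
        categorical_levels={"race": ("A", "B"), "sex": ("F", "M")},
    )


@pytest.fixture
def toy_frame():
    rng = np.random.default_rng(42)
    n = 120
    frame = pd.DataFrame(
        {
            "race": rng.choice(["A", "B"], n),
            "sex": rng.choice(["F", "M"], n),
            "age": rng.standard_normal(n),
            "score": rng.standard_normal(n),
        }
    )
    eta = 0.3 + 0.8 * frame["age"] - 0.5 * frame["score"]
    frame["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return frame


@pytest.fixture
def toy_dataset(toy_frame, toy_schema) -> Dataset:
    return from_dataframe(toy_frame, toy_schema)


def plain_design(X: np.ndarray, add_intercept: bool = True) -> DesignMatrix:
    """A bare numeric design matrix for unit-testing the GLM layer."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        cols = ("(Intercept)", *names)
    else:
        cols = tuple(names)
    return DesignMatrix(X=X, columns=cols, register={n: n for n in names}, case=None)
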