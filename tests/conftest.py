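import numpy as np
import pandas as pd
import pytest

from lbblmm import LMMData, build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def make_random_data(
    rng,
    n=5,
    n_i=4,
    p=3,
    q=2,
    cluster_constant=(),
    unbalanced=False,
):
    """Small random LMMData with a random intercept and q-1 random slopes."""
    sizes = (
        rng.integers(1, n_i + 2, size=n) if unbalanced
        else np.full(n, n_i)
    )
    N = int(sizes.sum())
    cluster_index = np.repeat(np.arange(n), sizes)
    X = rng.standard_normal((N, p))
    for r in cluster_constant:
        X[:, r] = rng.standard_normal(n)[cluster_index]
    Z = np.column_stack(
        [np.ones(N)] + [X[:, r] for r in range(q - 1)]
    )
    y = rng.standard_normal(N)
    return LMMData(
        y=y,
        X=X,
        Z=Z,
        cluster_index=cluster_index,
        cluster_labels=np.arange(n),
        covariate_names=[f"x{r + 1}" for r in range(p)],
        random_effect_spec=["(intercept)"] + [f"x{r + 1}" for r in range(q - 1)],
        has_random_intercept=True,
    )


@pytest.fixture
def small_data(rng):
    return make_random_data(rng)


@pytest.fixture
def growth_table(rng):
    """Longitudinal fixture: 27 children, 4 visits each, age + gender."""
    n, n_i = 27, 4
    rows = []
    for child in range(n):
        gender = child % 2
        intercept = rng.normal(0, 2)
        for visit in range(n_i):
            age = 8 + 2 * visit
            rows.append(
                {
                    "child": f"c{child:02d}",
                    "age": age,
                    "gender": gender,
                    "y": 17 + 0.5 * age - 2.0 * gender + intercept
                    + rng.normal(0, 1.2),
                }
            )
    return pd.DataFrame(rows).sample(frac=1.0, random_state=1).reset_index(
        drop=True
    )
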