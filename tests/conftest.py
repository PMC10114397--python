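import numpy as np
import pytest

from visioncouple import load_validation_cohort


@pytest.fixture(scope="session")
def validation_records():
    """The packaged 8-subject validation cohort, missing cell filled."""
    return load_validation_cohort(fill_missing=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def naive_critic_weights(X, convention="table", magnitude_policy="abs"):
    """Independent, loop-based evaluation of the CRITIC chain.

    Deliberately avoids numpy vectorisation and the package's own code:
    plain-Python means, SDs, correlations, independence coefficients,
    information volumes and normalised weights.
    """
    m = len(X)
    n = len(X[0])
    xbar = [sum(X[i][j] for i in range(m)) / m for j in range(n)]
    s = [
        (sum((X[i][j] - xbar[j]) ** 2 for i in range(m)) / (m - 1)) ** 0.5
        for j in range(n)
    ]
    Xs = [[(X[i][j] - xbar[j]) / s[j] for j in range(n)] for i in range(m)]
    sbar = [sum(Xs[i][j] for i in range(m)) / m for j in range(n)]
    R = [[0.0] * n for _ in range(n)]
    for k in range(n):
        for l in range(n):
            num = sum((Xs[i][k] - sbar[k]) * (Xs[i][l] - sbar[l]) for i in range(m))
            den_k = sum((Xs[i][k] - sbar[k]) ** 2 for i in range(m)) ** 0.5
            den_l = sum((Xs[i][l] - sbar[l]) ** 2 for i in range(m)) ** 0.5
            R[k][l] = num / (den_k * den_l)
    if convention == "table":
        v = [xbar[j] / s[j] for j in range(n)]
    else:
        v = [s[j] / xbar[j] for j in range(n)]
    eta = [sum(1.0 - abs(R[k][j]) for k in range(n)) for j in range(n)]
    if magnitude_policy == "abs":
        D = [abs(v[j]) * eta[j] for j in range(n)]
    else:
        D = [v[j] * eta[j] for j in range(n)]
    total = sum(D)
    return [d / total for d in D]
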