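import numpy as np
import pytest

from bbmeta import pre_eclampsia, pre_eclampsia_available, study_effects, toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture(scope="session")
def k3(toys):
    return toys["k3"]


@pytest.fixture(scope="session")
def k3_effects(k3):
    return study_effects(k3)


@pytest.fixture(scope="session")
def identical(toys):
    return toys["identical"]


@pytest.fixture(scope="session")
def zero_cell(toys):
    return toys["zero_cell"]


@pytest.fixture(scope="session")
def unbalanced(toys):
    return toys["unbalanced"]


@pytest.fixture(scope="session")
def diuretics():
    """The nine-trial pre-eclampsia dataset (skip if not packaged)."""
    if not pre_eclampsia_available():
        pytest.skip(
            "packaged pre-eclampsia dataset not available; worked-example "
            "checks are skipped"
        )
    return pre_eclampsia()


def brute_force_q(theta: np.ndarray, w: np.ndarray) -> float:
    """Independent double-loop evaluation of a weighted heterogeneity sum.

    Uses the pairwise identity sum_jk w_j w_k (t_j - t_k)^2 / (2 W) so it
    never forms the weighted mean that the implementation uses.
    """
    total = 0.0
    W = float(np.sum(w))
    for j in range(len(theta)):
        for k in range(len(theta)):
            total += w[j] * w[k] * (theta[j] - theta[k]) ** 2
    return total / (2.0 * W)
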