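import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from shiftvim.data import LongitudinalData, VarMeta

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_data():
    """Five subjects, two time points, two variables; subject 2 dies in interval 0.

    Values are laid out by hand so extraction results can be checked cell by
    cell.  Continuous variable x0 in (0,1), binary x1; x0 is missing for
    subject 4 at time 1.
    """
    n, J, K = 5, 2, 2
    cov = np.full((n, J, K), np.nan)
    flags = np.zeros((n, J, K), dtype=int)
    cov[:, 0, 0] = [0.2, 0.4, 0.6, 0.8, 0.5]
    cov[:, 0, 1] = [0, 1, 0, 1, 1]
    flags[:, 0, :] = 1
    cov[:, 1, 0] = [0.3, 0.5, 0.7, 0.9, np.nan]
    flags[:, 1, 0] = [1, 1, 1, 1, 0]
    cov[:, 1, 1] = [1, 0, 1, 0, 1]
    flags[:, 1, 1] = 1
    death = np.zeros((n, J), dtype=int)
    death[2, 0] = 1
    # dead subject's later measurements are degenerate
    cov[2, 1, :] = np.nan
    flags[2, 1, :] = 0
    return LongitudinalData(
        subject_id=np.arange(n),
        baseline=pd.DataFrame({"age": [0.1, 0.3, 0.5, 0.7, 0.9]}),
        times=np.array([0.0, 6.0]),
        covariates=cov,
        miss_flags=flags,
        death=death,
        var_meta=[
            VarMeta("x0", "continuous", "treatment"),
            VarMeta("x1", "binary", "treatment"),
        ],
    )
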