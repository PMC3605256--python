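import numpy as np
import pandas as pd
import pytest

from rarecnv.cnv_core import SampleSheet


def make_sheet(n_case, n_control, cohort="c1", platform="p1", n_cov=0, rng=None):
    rows = []
    for i in range(n_case):
        rows.append({"sample_id": f"{cohort}_case_{i:04d}", "status": "case",
                     "cohort": cohort, "platform": platform})
    for i in range(n_control):
        rows.append({"sample_id": f"{cohort}_ctrl_{i:04d}", "status": "control",
                     "cohort": cohort, "platform": platform})
    df = pd.DataFrame(rows)
    if n_cov:
        rng = rng or np.random.default_rng(0)
        for j in range(n_cov):
            df[f"cov{j+1}"] = rng.normal(size=len(df))
    return SampleSheet(df)


@pytest.fixture
def small_sheet():
    return make_sheet(5, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
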