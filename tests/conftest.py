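import numpy as np
import pandas as pd
import pytest

from surfmon import SurveyDesign, make_truth


@pytest.fixture()
def small_design():
    return SurveyDesign(n_sites=6)


@pytest.fixture()
def small_truth(small_design):
    return make_truth(small_design, n_species=8, seed=11)


@pytest.fixture()
def community_fixture():
    """15-row (5 sites x 3 methods) binary community matrix.

    Deterministic generation; per-method detection rates differ slightly so
    both factors carry some signal.
    """
    rng = np.random.default_rng(42)
    rows, labels = [], []
    for si in range(5):
        for m in ["seine", "bruv", "edna"]:
            p = 0.3 + 0.15 * (m == "edna") + 0.05 * si
            rows.append((rng.random(12) < p).astype(int))
            labels.append((f"site{si + 1}", m))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(labels, names=["site", "method"])
    )
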