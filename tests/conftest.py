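import numpy as np
import pandas as pd
import pytest

from hemideg import CountMatrix, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    data = pd.DataFrame(
        [[0, 5], [2, 0], [7, 1]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
    return CountMatrix(data)


def make_design(region="CeA", n_per_group=2, regions=None):
    rows = []
    for reg in regions or [region]:
        for condition in ("Sham", "SNL"):
            for side in ("Left", "Right"):
                for i in range(1, n_per_group + 1):
                    rows.append({
                        "sample_id": f"{reg}_{condition}_{side}_s{i}",
                        "region": reg, "condition": condition,
                        "side": side, "subject": f"{condition}{i}",
                    })
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def balanced_design():
    return make_design()
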