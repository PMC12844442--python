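import numpy as np
import pandas as pd
import pytest

from microscale import OtuTable, SampleFrame


@pytest.fixture
def tiny_table() -> OtuTable:
    """5 samples x 4 taxa with grand-total taxon shares 0.5/0.3/0.15/0.05."""
    counts = np.array(
        [
            [10, 6, 3, 1],
            [10, 6, 3, 1],
            [10, 6, 3, 1],
            [10, 6, 3, 1],
            [10, 6, 3, 1],
        ]
    )
    return OtuTable(counts, [f"s{i}" for i in range(5)], ["t1", "t2", "t3", "t4"])


def flat_frame(n: int, group: str = "G", area: float = 0.25) -> SampleFrame:
    """n samples at one level of one plot (no spatial structure needed)."""
    rows = [
        {
            "sample_id": f"{group}_s{i}",
            "group": group,
            "plot_id": f"{group}_P1",
            "x": 0.0,
            "y": 0.0,
            "level": 0,
            "area": area,
        }
        for i in range(n)
    ]
    return SampleFrame(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
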