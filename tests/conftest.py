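import numpy as np
import pandas as pd
import pytest

from crisprai_screen import screen_scoring as ss
from crisprai_screen import synthetic_data as sd


@pytest.fixture(scope="session")
def null_screen_scored():
    """Scored null screen (all beta = epsilon = 0), 200 pairs x 3 replicates."""
    truth = sd.example_screen_truth(seed=42)
    counts, _ = sd.simulate_sort_screen(truth)
    return ss.score_screen(counts)


@pytest.fixture(scope="session")
def small_norm():
    """Log-normalized homogeneous expression matrix, 80 cells x 60 genes."""
    from crisprai_screen import perturbseq_modes as pm

    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.4, size=(80, 60)) + 1,
        index=[f"c{i}" for i in range(80)],
        columns=[f"g{j:02d}" for j in range(60)],
    )
    return pm.log_normalize(counts)


@pytest.fixture()
def toy_screen_counts():
    """10-pair, 2-population toy count table with closed-form expectations."""
    rows = []
    # per-pair totals: 600, 550, 500, 450, 360, 340, 320, 310, 300, 80
    # -> p8 sits exactly at the 300-read boundary (removed, strict), p9 low
    reads = {
        "POS": [500, 400, 300, 200, 180, 170, 160, 155, 150, 40],
        "NEG": [100, 150, 200, 250, 180, 170, 160, 155, 150, 40],
    }
    for i in range(10):
        is_ntc = i >= 6
        for pop in ("POS", "NEG"):
            rows.append(
                {
                    "pair_id": f"p{i}",
                    "guide1": f"g{i}",
                    "guide2": "NTC",
                    "is_ntc": is_ntc,
                    "population": pop,
                    "replicate": 1,
                    "reads": reads[pop][i],
                }
            )
    return pd.DataFrame(rows)
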