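import numpy as np
import pandas as pd
import pytest

from betascape.core import CommunityTable, SampleMetadata
from betascape.simulate import SimConfig, simulate_paired_design


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    counts = rng.integers(0, 50, size=(12, 20))
    counts[:, 0] += 1  # keep every row non-empty
    df = pd.DataFrame(counts,
                      index=[f"s{i}" for i in range(12)],
                      columns=[f"f{j}" for j in range(20)])
    return CommunityTable(df, feature_kind="asv", normalization="raw")


@pytest.fixture
def paired_survey():
    """Small paired design: 6 sites x 2 land uses x 3 replicates."""
    cfg = SimConfig(n_sites=6, n_replicates=3, n_features=120, depth=800,
                    seed=7)
    return simulate_paired_design(cfg)


@pytest.fixture
def metadata_frame():
    rows = []
    for site in (1, 2, 3):
        for lu in ("AS", "NS"):
            for rep in (1, 2):
                rows.append({
                    "sample_id": f"S{site}_{lu}_{rep}",
                    "site_id": site, "land_use": lu, "replicate": rep,
                    "latitude": 44.0 + site, "longitude": 125.0,
                    "pH": 6.5 + 0.1 * site,
                })
    return pd.DataFrame(rows)


@pytest.fixture
def metadata(metadata_frame):
    return SampleMetadata(metadata_frame)
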