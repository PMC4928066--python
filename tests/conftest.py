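import numpy as np
import pandas as pd
import pytest

from taxadecay.core_tables import OtuTable, SampleFrame, SignalTable
from taxadecay.synthetic import scaled_config, study_preset


@pytest.fixture
def tiny_otu() -> OtuTable:
    counts = pd.DataFrame(
        [[5, 0, 3, 1], [2, 4, 0, 1], [1, 1, 6, 0]],
        index=["s1", "s2", "s3"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    taxonomy = pd.Series(
        {
            "otu1": "k__Bacteria; p__Acidobacteria; c__X",
            "otu2": "k__Bacteria; p__Acidobacteria; c__Y",
            "otu3": "k__Bacteria; p__Proteobacteria; c__Z",
            "otu4": "unclassified",
        }
    )
    return OtuTable(counts, taxonomy)


@pytest.fixture
def tiny_frame() -> SampleFrame:
    return SampleFrame(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "site_id": ["A", "A", "B", "B"],
                "latitude": [30.0, 30.01, 35.0, 35.02],
                "longitude": [110.0, 110.0, 111.0, 111.01],
                "elevation": [500.0, 520.0, 900.0, 910.0],
            }
        )
    )


@pytest.fixture
def tiny_signals() -> SignalTable:
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(1, 5)]
    probes = [f"pr{j}" for j in range(1, 7)]
    inten = pd.DataFrame(
        rng.uniform(1, 10, size=(4, 6)), index=samples, columns=probes
    )
    category = pd.Series(
        ["FTHFS", "FTHFS", "ureC", "ureC", "ppx", "ppx"], index=probes
    )
    site_of = pd.Series(["A", "A", "B", "B"], index=samples)
    return SignalTable(inten, category, site_of)


@pytest.fixture(scope="session")
def small_triple():
    """A reduced but structurally complete synthetic study."""
    cfg = scaled_config()
    return study_preset(seed=11, config=cfg), cfg
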