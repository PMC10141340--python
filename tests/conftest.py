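import numpy as np
import pandas as pd
import pytest

from breathlink import FeatureTable, SampleMetadata, StudyDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_voc_table():
    data = pd.DataFrame(
        [[100.0, 0.0, 3000.0], [250.0, 40.0, 0.0], [0.0, 55.0, 1200.0]],
        index=["s1", "s2", "s3"],
        columns=["Toluene", "Benzene", "1-Octanol"],
    )
    return FeatureTable(data, "voc")


@pytest.fixture
def small_dataset(rng):
    """Tiny two-group paired dataset with one perfectly linked VOC/taxon pair."""
    n = 12
    samples = [f"s{i}" for i in range(n)]
    shared = rng.lognormal(2.0, 0.5, n)
    voc = pd.DataFrame(
        {
            "VOC_link": shared,
            "VOC_a": rng.lognormal(3.0, 1.0, n),
            "VOC_b": rng.lognormal(3.0, 1.0, n),
        },
        index=samples,
    )
    taxa_raw = pd.DataFrame(
        {
            "t_link": shared,
            "t_a": rng.lognormal(0.0, 1.0, n),
            "t_b": rng.lognormal(0.0, 1.0, n),
        },
        index=samples,
    )
    taxa = taxa_raw.div(taxa_raw.sum(axis=1), axis=0)
    meta = pd.DataFrame(
        {"group": ["cancer"] * 6 + ["control"] * 6},
        index=pd.Index(samples, name="sample_id"),
    )
    return StudyDataset(
        FeatureTable(voc, "voc"), FeatureTable(taxa, "taxon"), SampleMetadata(meta)
    )
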