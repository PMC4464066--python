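import numpy as np
import pytest

from mwasnet import (
    FeatureTable,
    choline_casestudy_fixture,
)


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 features x 4 samples, deterministic values."""
    rng = np.random.default_rng(7)
    return FeatureTable(
        mz=np.array([104.1062, 184.0719, 500.25]),
        rt=np.array([51.0, 417.0, 320.0]),
        intensities=rng.uniform(1e4, 1e6, size=(3, 4)),
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def toy_table_file(tmp_path, toy_table):
    path = tmp_path / "features.tsv"
    lines = ["mz\ttime\ts1\ts2\ts3\ts4"]
    for i in range(toy_table.n_features):
        cells = [f"{toy_table.mz[i]}", f"{toy_table.rt[i]}"]
        cells += [f"{v:.3f}" for v in toy_table.intensities[i]]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def choline_fixture():
    """Session-cached choline-like case study (anchor + 13C + lipid module)."""
    return choline_casestudy_fixture(seed=11)
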