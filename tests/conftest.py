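import numpy as np
import pandas as pd
import pytest

from metaboqc import PeakTable, SimulationConfig


def make_peak_table(
    intensities: np.ndarray,
    sample_classes: list[str],
    batches=None,
    passages=None,
    treatments=None,
    feature_ids=None,
) -> PeakTable:
    """Hand-build a small peak table; study-sample labels default to one cell."""
    n_feat, n_samp = intensities.shape
    fids = feature_ids or [f"F{i + 1}" for i in range(n_feat)]
    sids = [f"X{j + 1}" for j in range(n_samp)]
    samples = pd.DataFrame(
        {
            "injection_order": np.arange(1, n_samp + 1),
            "sample_class": sample_classes,
            "batch": batches or [("B1" if c == "sample" else None) for c in sample_classes],
            "passage": passages or [("P18" if c == "sample" else None) for c in sample_classes],
            "treatment": treatments
            or [("CA" if c == "sample" else None) for c in sample_classes],
        },
        index=pd.Index(sids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "mz": np.linspace(100, 500, n_feat),
            "rt": np.linspace(60, 600, n_feat),
            "ion_mode": "positive",
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return PeakTable(pd.DataFrame(intensities, index=fids, columns=sids), samples, features)


@pytest.fixture
def toy_table() -> PeakTable:
    """3 features x 4 study samples, no QCs/blanks."""
    rng = np.random.default_rng(0)
    return make_peak_table(rng.uniform(100, 1000, (3, 4)), ["sample"] * 4)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Compact full-factorial design used across simulation-backed tests."""
    return SimulationConfig(
        n_features=30,
        n_batches=2,
        n_passages=2,
        n_treatments=3,
        replicates_per_cell=2,
        qc_interval=4,
        n_blanks=3,
        seed=11,
    )
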