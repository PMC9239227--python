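import numpy as np
import pytest

from dualenrich import community as cm
from dualenrich import gas as gk
from dualenrich import synth


@pytest.fixture(scope="session")
def enrichment_dataset() -> synth.EnrichmentDataset:
    """Default-noise synthetic dual-enrichment dataset (seeded)."""
    return synth.generate_enrichment_dataset(synth.CommunitySpec(seed=11))


@pytest.fixture(scope="session")
def anoxic_gas_run():
    """Noise-free anoxic two-population incubation and its corrected series."""
    spec = synth.GasSimSpec(o2_dose=0.0, noise_cv=0.0, seed=5)
    raw, true = synth.generate_gas_series(spec)
    corrected = gk.correct_series(raw, spec.vial)
    return spec, raw, true, corrected


@pytest.fixture(scope="session")
def toy_relative():
    """Small handmade relative-abundance table (4 samples x 6 OTUs)."""
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(4, 6))
    counts[:, 0] += 5  # no all-zero rows
    import pandas as pd

    df = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(4)],
        columns=[f"OTU{i}" for i in range(6)],
        dtype=float,
    )
    return df.div(df.sum(axis=1), axis=0)
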