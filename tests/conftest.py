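import numpy as np
import pandas as pd
import pytest

import toxscreen as tx


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = tx.SimulationConfig(
        n_transcripts=300,
        n_spiked_toxins=15,
        seed=42,
        length_range=(200, 600),
    )
    return tx.generate_study(config=cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    return tx.ToxinDiscoveryPipeline().fit(small_study.to_study_data(), seed=42)


def build_matrix(counts: dict, design: dict, eff_length: dict | None = None):
    """ExpressionMatrix from plain dicts (counts: transcript -> {lib: n})."""
    df = pd.DataFrame(counts).T
    df = df[list(design)]
    if eff_length is None:
        eff_length = {t: 1000.0 for t in df.index}
    return tx.ExpressionMatrix(
        counts=df.astype(float),
        eff_length=pd.Series(eff_length),
        design=pd.Series(design),
    )


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
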