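import numpy as np
import pytest

from strmixlr.datamodel import FrequencyTable


@pytest.fixture
def four_allele_locus() -> dict[str, float]:
    """A hand-built locus with frequencies summing exactly to 1."""
    return {"8": 0.1, "9": 0.2, "10": 0.3, "11": 0.4}


@pytest.fixture
def small_table(four_allele_locus) -> FrequencyTable:
    return FrequencyTable(
        population="POP-A",
        n_individuals=500,
        freqs={"D3S1358": dict(four_allele_locus), "VWA": {"14": 0.5, "15": 0.5}},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
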