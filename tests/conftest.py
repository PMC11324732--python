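import numpy as np
import pandas as pd
import pytest

from heatnuc.quant_io import AbundanceMatrix, SampleDesign


@pytest.fixture
def design() -> SampleDesign:
    return SampleDesign.default(3)


@pytest.fixture
def design_file(tmp_path, design):
    path = tmp_path / "design.tsv"
    design.to_frame().to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_log2_matrix(rng, design) -> AbundanceMatrix:
    data = pd.DataFrame(
        rng.normal(20.0, 1.0, size=(200, len(design))),
        index=[f"P{i:04d}" for i in range(200)],
        columns=design.samples,
    )
    return AbundanceMatrix(data, scale="log2")
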