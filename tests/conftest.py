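import numpy as np
import pandas as pd
import pytest

from bloodbrain.io import BetaMatrix, SampleSheet, WeightTable


@pytest.fixture
def toy_matrix() -> BetaMatrix:
    values = pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]],
        index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return BetaMatrix(values=values)


@pytest.fixture
def toy_weights() -> WeightTable:
    return WeightTable(trait="smoking", weights=pd.Series([0.5, -0.25], index=["cg01", "cg02"]))


def random_beta_matrix(rng: np.random.Generator, n_probes: int = 20, n_samples: int = 6,
                       missing_frac: float = 0.0) -> BetaMatrix:
    vals = rng.uniform(0.001, 0.999, (n_probes, n_samples))
    if missing_frac > 0:
        mask = rng.random(vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return BetaMatrix(values=pd.DataFrame(vals, index=pd.Index(probes, name="probe_id"), columns=samples))


def make_sheet(rows: list[tuple[str, str, str, str]]) -> SampleSheet:
    return SampleSheet(frame=pd.DataFrame(rows, columns=["sample_id", "individual_id", "tissue", "recorded_sex"]))
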