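import numpy as np
import pandas as pd
import pytest

from tesla_twas.simulator import SimulationScenario, prepare_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_data():
    """Realized default study structure (3 ancestries x 4 cohorts, J=10)."""
    return prepare_scenario(SimulationScenario(seed=42))


@pytest.fixture
def summary_file(tmp_path):
    """Factory writing a cohort summary TSV and returning its path."""

    def _write(rows, name="cohort.tsv", columns=None):
        df = pd.DataFrame(rows)
        if columns:
            df = df.rename(columns=columns)
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write


def make_rows(n=5, s=1e-2, base_pos=100):
    return [
        {
            "variant_id": f"1:{base_pos + i}:A:G",
            "chrom": "1",
            "pos": base_pos + i,
            "ref": "A",
            "alt": "G",
            "eaf": 0.2 + 0.1 * (i % 3),
            "b": 0.01 * (i - 2),
            "s": s,
            "n": 1.0 / s**2,
        }
        for i in range(n)
    ]
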