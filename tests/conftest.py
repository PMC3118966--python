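import numpy as np
import pandas as pd
import pytest

from dmhprep.io import TwoColorArray
from dmhprep.synthetic import SyntheticConfig, generate_dataset

#: Desk-scale dataset used by the integration-style unit tests: the full
#: structure of the default presets (controls, housekeeping and
#: methylated islands) at reduced counts.
SMALL_CONFIG = SyntheticConfig(
    n_arrays=8,
    n_methylated_islands=10,
    n_housekeeping_islands=12,
    n_other_islands=6,
    probes_per_island=6,
    n_control_probes=60,
)


@pytest.fixture(scope="session")
def small_dataset():
    genome, annotation, arrays, truth = generate_dataset(SMALL_CONFIG, seed=11)
    return {
        "genome": genome,
        "annotation": annotation,
        "arrays": arrays,
        "truth": truth,
        "config": SMALL_CONFIG,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_array(Rf, Gf, Rb=None, Gb=None, array_id="arr"):
    n = len(Rf)
    return TwoColorArray(
        array_id=array_id,
        data=pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "Rf": Rf,
                "Gf": Gf,
                "Rb": Rb if Rb is not None else np.zeros(n),
                "Gb": Gb if Gb is not None else np.zeros(n),
            }
        ),
    )


@pytest.fixture()
def feature_table_file(tmp_path):
    """Write a feature table file in the default dialect; returns a factory."""

    def _write(rows, name="array1.tsv", header=None):
        header = header or ["ProbeName", "rMeanSignal", "gMeanSignal", "rBGMeanSignal", "gBGMeanSignal"]
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
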