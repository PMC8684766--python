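import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from integratome.simulate import StudyConfig, generate_study, generate_study_data

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: smaller than the default study but same design; shared across tests
SMALL = StudyConfig(
    n_genes=120,
    intergenic_probes=40,
    n_de_genes=12,
    n_tfs=10,
    probes_per_tf=30,
    n_shifted_tfs=2,
    validation_set_size=20,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study_data(SMALL, seed=11)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    paths = generate_study(SMALL, seed=7, outdir=out)
    return out, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_sheet(n_case, n_control, tissue="SAT"):
    rows = [(f"C{i}_{tissue}", "case", tissue) for i in range(n_case)]
    rows += [(f"K{i}_{tissue}", "control", tissue) for i in range(n_control)]
    from integratome.io import SampleSheet

    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "group", "tissue"]))
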