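import os

import pytest
from hypothesis import HealthCheck, settings

from mirssr.pipeline import run_mirna_pipeline, run_ssr_pipeline
from mirssr.simulate import generate_fixture, write_fixture

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: the standard study-condition fixture seed used throughout the suite
FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def std_fixture():
    return generate_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def std_fixture_paths(std_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(std_fixture, str(outdir))


@pytest.fixture(scope="session")
def mirna_result(std_fixture_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mirna_run")
    return run_mirna_pipeline(std_fixture_paths["transcripts"],
                              std_fixture_paths["matures"], out_dir=str(outdir))


@pytest.fixture(scope="session")
def ssr_result(std_fixture_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("ssr_run")
    return run_ssr_pipeline(std_fixture_paths["transcripts"], out_dir=str(outdir))
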