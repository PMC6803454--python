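import pathlib

import pytest
from hypothesis import settings

from metanno.fixtures import generate_fixture_set
from metanno.pipeline import RunConfig, run_pipeline

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

FIXTURE_SEED = 101


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One self-consistent synthetic input directory shared by the suite."""
    d = tmp_path_factory.mktemp("fixture") / "inputs"
    return generate_fixture_set(d, seed=FIXTURE_SEED, n_contigs=8, decoy_rate=0.5)


@pytest.fixture(scope="session")
def pipeline_out(fixture_set, tmp_path_factory):
    """A completed pipeline run over the shared fixture set."""
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = RunConfig(input_dir=fixture_set.outdir, outdir=out)
    bundle = run_pipeline(cfg)
    return out, bundle, fixture_set


def snapshot(outdir: pathlib.Path, exclude=("run.log",)) -> dict:
    """Byte-level snapshot of a pipeline output directory."""
    return {
        p.name: p.read_bytes()
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in exclude
    }
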