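import pytest

from neopipe.pipeline import PipelineInputs, run_pipeline
from neopipe.simulate import FixtureSpec, generate_fixture

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("toydata")
    generate_fixture(FixtureSpec(seed=FIXTURE_SEED), out)
    return out


@pytest.fixture(scope="session")
def ground_truth(fixture_dir):
    import json
    return json.loads((fixture_dir / "ground_truth.json").read_text())


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir):
    inputs = PipelineInputs.from_dir(fixture_dir)
    return run_pipeline(inputs, seed=FIXTURE_SEED)
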