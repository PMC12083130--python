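import pytest
from hypothesis import HealthCheck, settings

from dvtpipe import pipeline, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory):
    """One deterministic mini bundle shared by read-only tests."""
    out = tmp_path_factory.mktemp("bundle") / "mini42"
    truth = simulate.generate_bundle(simulate.mini(42), out)
    return out, truth


@pytest.fixture(scope="session")
def mini_report(mini_bundle, tmp_path_factory):
    bundle, truth = mini_bundle
    out = tmp_path_factory.mktemp("run") / "out"
    config = pipeline.PipelineConfig.from_bundle(bundle, out)
    return pipeline.run(config), truth
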