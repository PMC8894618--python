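import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[
        HealthCheck.too_slow,
        # read-only fixtures shared across generated examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def worked_example_paths():
    """(deg_tsv, annotation_tsv, synonym_tsv) of the packaged fixtures."""
    from degconcord import fixture_worked_example

    return fixture_worked_example()


@pytest.fixture
def write_tsv(tmp_path):
    """Write an inline TSV under tmp_path and return its path."""

    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
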