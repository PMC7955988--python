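import pytest
from hypothesis import HealthCheck, settings

from medlinedb import fixtures as fx
from medlinedb.build import build_baseline
from medlinedb.db import Database, init_tables
from medlinedb.update import update_database

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def db():
    d = Database.connect(":memory:")
    init_tables(d)
    yield d
    d.close()


@pytest.fixture
def make_corpus(tmp_path):
    """Generate a random scripted corpus; returns (script, baseline, updates)."""

    def _make(seed, **kwargs):
        script = fx.random_script(seed, **kwargs)
        paths = fx.generate(script, tmp_path / f"corpus{seed}")
        return (
            script,
            paths[: script.n_baseline_files],
            paths[script.n_baseline_files :],
        )

    return _make


@pytest.fixture
def run_pipelines():
    """Build baseline then apply update files on a fresh in-memory database."""

    def _run(baseline, updates, worker_count=1, per_file_batches=False):
        d = Database.connect(":memory:")
        init_tables(d)
        if baseline:
            build_baseline(baseline, d, worker_count=worker_count)
        if per_file_batches:
            for f in updates:
                update_database([f], d)
        elif updates:
            update_database(updates, d)
        return d

    return _run
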