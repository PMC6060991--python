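import pandas as pd
import pytest

from dgeflow.synthetic_data import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_stats")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_pairs")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_flowering")


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One small simulated study with a completed pipeline run."""
    from dgeflow.pipeline import PipelineConfig, make_demo, run_pipeline

    outdir = tmp_path_factory.mktemp("demo")
    paths = make_demo(seed=11, outdir=outdir)
    config = PipelineConfig.from_yaml(paths["config"])
    manifest = run_pipeline(config)
    return {"paths": paths, "config": config, "manifest": manifest, "outdir": outdir}
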