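import numpy as np
import pytest

from orfdecay.pipeline import RunConfig, run
from orfdecay.synthetic_data import SimConfig, make_ancestral_locus


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One zero-divergence demo pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("demo")
    report = run(RunConfig(seed=0, outdir=str(outdir), divergence=0.0))
    assert report.ok, [(s.stage, s.warnings) for s in report.stages]
    return report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_locus():
    """A small single-scenario ancestral locus (gene model, record, copy)."""
    cfg = SimConfig(seed=7, tree="(A:0.0,B:0.0)R;")
    model, record, copy = make_ancestral_locus(cfg)
    return cfg, model, record, copy


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
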