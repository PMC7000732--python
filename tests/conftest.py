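import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from bridgedms.fastq_io import SequenceRead
from bridgedms.sim_dms import SimConfig, default_anchor_specs, generate_library


@pytest.fixture
def anchor_specs():
    return default_anchor_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pool():
    cfg = SimConfig(seed=7, library_size=300)
    return cfg, generate_library(cfg, np.random.default_rng(7))


def make_read(
    x=100,
    y=200,
    mate=1,
    bases="ACGT",
    quals=None,
    tile=11101,
    flowcell="FC",
    lane=1,
    instrument="M",
    run=1,
):
    if quals is None:
        quals = (40,) * len(bases)
    raw_id = f"{instrument}:{run}:{flowcell}:{lane}:{tile}:{x}:{y} {mate}:N:0:1"
    return SequenceRead(
        raw_id=raw_id,
        instrument=instrument,
        run=run,
        flowcell=flowcell,
        lane=lane,
        tile=tile,
        x=x,
        y=y,
        mate=mate,
        bases=bases,
        quals=tuple(quals),
    )
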