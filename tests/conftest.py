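import numpy as np
import pandas as pd
import pytest

from fermstage.io_formats import REPLICATES, STAGES, SampleDesign


def make_design(n_replicates: int = 3, reads: int = 20_000_000,
                jitter=None) -> SampleDesign:
    """Balanced 5-stage design with optional per-sample read counts."""
    rows = []
    i = 0
    for stage in STAGES:
        for rep in REPLICATES[:n_replicates]:
            r = reads if jitter is None else jitter[i]
            rows.append((f"{stage}-{rep}", stage, rep, r))
            i += 1
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "stage", "replicate",
                       "total_mapped_reads"]))


@pytest.fixture
def design() -> SampleDesign:
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
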