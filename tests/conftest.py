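import numpy as np
import pytest

from stabkit.design import MutationCandidate


def make_candidate(position, wt="A", mut="V", ddg=-1.5, dtm=None, source="energy"):
    return MutationCandidate(
        position=position,
        wt=wt,
        mut=mut,
        source=source,
        ddg_pred1=ddg,
        ddg_pred2=ddg,
        passed_ddg=True,
        passed_conservation=True,
        passed_site_exclusion=True,
        measured_dtm=dtm,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
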