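import numpy as np
import pandas as pd
import pytest

from circscape.circquant import CircCandidate, JunctionCountSet


def make_jcs(bsj, donor=None, acceptor=None, library_sizes=None, conditions=None):
    """Build a small JunctionCountSet from plain matrices."""
    bsj = np.atleast_2d(np.asarray(bsj))
    n, m = bsj.shape
    donor = np.atleast_2d(np.asarray(donor)) if donor is not None else np.zeros_like(bsj)
    acceptor = (
        np.atleast_2d(np.asarray(acceptor)) if acceptor is not None else np.zeros_like(bsj)
    )
    library_sizes = (
        np.asarray(library_sizes, dtype=float)
        if library_sizes is not None
        else np.full(m, 1e6)
    )
    conditions = list(conditions) if conditions is not None else ["c1"] * m
    candidates = [
        CircCandidate(chrom="chr1", start=1000 * (i + 1), end=1000 * (i + 1) + 500,
                      strand="+")
        for i in range(n)
    ]
    ids = [c.id for c in candidates]
    cols = [f"s{j}" for j in range(m)]
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, m + 1)),
            "library_size": library_sizes,
        },
        index=pd.Index(cols, name="sample"),
    )
    return JunctionCountSet(
        candidates=candidates,
        samples=samples,
        bsj=pd.DataFrame(bsj, index=ids, columns=cols),
        donor_linear=pd.DataFrame(donor, index=ids, columns=cols),
        acceptor_linear=pd.DataFrame(acceptor, index=ids, columns=cols),
    )


@pytest.fixture
def jcs_factory():
    return make_jcs
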