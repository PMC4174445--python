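import numpy as np
import pandas as pd
import pytest

from rateseq import CountMatrix, RunConfig


def build_count_matrix(gene_rows, spike_rows, replicates):
    """Assemble a CountMatrix from {id: [counts...]} dicts and a column spec.

    ``replicates`` is a list of (replicate, [times...]) in column order.
    """
    cols = pd.MultiIndex.from_tuples(
        [(rep, float(t)) for rep, times in replicates for t in times],
        names=["replicate", "time_min"],
    )
    rows = {**gene_rows, **spike_rows}
    mat = pd.DataFrame(
        np.array([rows[k] for k in rows], dtype=float), index=list(rows), columns=cols
    )
    return CountMatrix(counts=mat, spikein_ids=list(spike_rows))


@pytest.fixture
def small_cm():
    """3 genes, 2 spike-ins, one replicate at 3/5/10 min."""
    return build_count_matrix(
        gene_rows={
            "g1": [100, 200, 300],
            "g2": [50, 100, 150],
            "g3": [10, 20, 30],
        },
        spike_rows={"sp1": [50, 50, 50], "sp2": [25, 25, 25]},
        replicates=[("rep1", [3, 5, 10])],
    )


@pytest.fixture
def cfg():
    return RunConfig(n_bootstrap=50, rng_seed=0)
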