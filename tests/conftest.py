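import numpy as np
import pytest

import mutstab as ms
from mutstab.msa import compute_weights
from mutstab.potts import fit_potts, sample_msa


@pytest.fixture(scope="session")
def table1():
    return ms.load_msh2_table1()


@pytest.fixture(scope="session")
def small_matrix():
    return ms.gen_ddg_matrix(ms.SyntheticConfig(seed=11, n_positions=30))


@pytest.fixture(scope="session")
def potts_recovery():
    """Truth model, a Gibbs sample from it, and the refit — shared across tests."""
    truth = ms.gen_potts_truth(length=8, alphabet="ACDE", seed=3)
    msa = sample_msa(truth, 2000, seed=103)
    weights = compute_weights(msa, theta=1.0)
    fitted = fit_potts(msa, weights, lambda_h=0.01)
    return truth, msa, fitted


def all_substitution_scores(model, msa) -> np.ndarray:
    """Scores of every substitution at every column, in a fixed order."""
    q = msa.query_row()
    out = []
    for col in range(msa.length):
        for a in range(len(msa.alphabet)):
            if a == q[col]:
                continue
            s = model.h[col, q[col]] - model.h[col, a]
            for j in range(model.length):
                if j != col:
                    s += model.J[col, j, q[col], q[j]] - model.J[col, j, a, q[j]]
            out.append(s)
    return np.array(out)
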