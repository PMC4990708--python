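import numpy as np
import pytest

from bitelever import parse_newick


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_five():
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


def dense_bm_loglik(tree, traits, sigma2, root_state):
    """Independent BM oracle: explicit covariance + multivariate normal.

    The covariance entry for tips i, j is sigma2 times the duration of
    their shared root-ward path, computed from root-to-tip node paths —
    no code shared with the pruning implementation.
    """
    from scipy.stats import multivariate_normal

    labels = tree.tip_labels
    paths = {}
    for lab in labels:
        nid = tree.tip_id(lab)
        path = []
        while tree.parent(nid) is not None:
            path.append(nid)
            nid = tree.parent(nid)
        paths[lab] = set(path)
    n = len(labels)
    cov = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = paths[a] & paths[b]
            cov[i, j] = sigma2 * sum(tree.duration(k) for k in shared)
    x = np.array([traits[lab] for lab in labels])
    return float(
        multivariate_normal(mean=np.full(n, root_state), cov=cov).logpdf(x)
    )


@pytest.fixture
def bm_oracle():
    return dense_bm_loglik
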