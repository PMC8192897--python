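import numpy as np
import pandas as pd
import pytest

from mergm import AttributeTable, MultilevelNetwork, load_multilevel_network


@pytest.fixture
def g3():
    """Three respondents, arcs {1→2, 2→1, 2→3}, groups g1={1,2}, g2={2,3}.

    Attributes: knowledge x = (1, 2, 4), gender b = (1, 0, 1).
    """
    return load_multilevel_network(
        [("1", "2"), ("2", "1"), ("2", "3")],
        [("1", "g1"), ("2", "g1"), ("2", "g2"), ("3", "g2")],
        [
            {"student": "1", "respondent": 1, "gender": 1, "ps": 1,
             "knowledge": 1.0, "norms": 1.0, "talking": 2.0},
            {"student": "2", "respondent": 1, "gender": 0, "ps": 0,
             "knowledge": 2.0, "norms": 3.0, "talking": 1.0},
            {"student": "3", "respondent": 1, "gender": 1, "ps": 1,
             "knowledge": 4.0, "norms": 2.0, "talking": 5.0},
        ],
    )


def make_random_network(n=6, m=2, density=0.3, resp_p=0.8, seed=0, max_out=6):
    """Small random multilevel network + attribute table for oracle sweeps."""
    r = np.random.default_rng(seed)
    resp = r.random(n) < resp_p
    if not resp.any():
        resp[0] = True
    y = (r.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(y, 0)
    y[~resp, :] = 0
    # trim to the nomination cap, keeping lowest-index receivers
    for i in np.nonzero(resp)[0]:
        recv = np.nonzero(y[i])[0]
        if recv.size > max_out:
            y[i, recv[max_out:]] = 0
    z = (r.random((n, m)) < 0.5).astype(np.int8)
    students = [f"s{i}" for i in range(n)]
    net = MultilevelNetwork(students, [f"g{j}" for j in range(m)], y, z, resp, max_out=max_out)
    attrs = AttributeTable(pd.DataFrame({
        "respondent": resp.astype(int),
        "gender": (r.random(n) < 0.5).astype(float),
        "ps": (r.random(n) < 0.2).astype(float),
        "knowledge": r.normal(5, 1.5, n),
        "norms": r.normal(7, 1.2, n),
        "talking": r.normal(4, 1.8, n),
    }, index=students))
    return net, attrs


def assert_constraints(y, net):
    """Global validator: structural zeros and the nomination cap hold."""
    y = np.asarray(y)
    assert y[~net.respondent].sum() == 0, "arc sent by a non-respondent"
    assert np.diag(y).sum() == 0, "self-arc"
    assert y[net.respondent].sum(axis=1).max(initial=0) <= net.max_out, \
        "respondent out-degree above the nomination cap"
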