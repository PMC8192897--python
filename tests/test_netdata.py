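import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mergm import (
    NetworkDataError,
    free_tie_variables,
    load_multilevel_network,
    read_school,
    summarize,
    write_school,
)
from mergm.netdata import write_matrices


def test_empty_inputs_give_empty_network():
    net, attrs = load_multilevel_network([], [], [])
    assert net.n == 0 and net.n_groups == 0
    assert len(free_tie_variables(net)) == 0
    s = summarize(net, attrs)
    assert s["students"] == s["arcs"] == 0
    assert s["density"] == 0.0  # documented convention on an empty free set


def test_basic_load_counts(g3):
    net, attrs = g3
    assert net.n == 3 and net.n_groups == 2
    assert net.y.sum() == 3 and net.z.sum() == 4
    assert summarize(net)["density"] == pytest.approx(0.5)


def test_structural_zero_rule_rejected_in_strict_mode():
    records = [{"student": s, "respondent": int(s != "d"), "gender": 0}
               for s in "abcd"]
    with pytest.raises(NetworkDataError, match="non-respondent"):
        load_multilevel_network([("d", "a")], [], records, strict=True)
    # non-strict mode drops the record instead
    net, _ = load_multilevel_network([("d", "a"), ("a", "b")], [], records, strict=False)
    assert net.y.sum() == 1


def test_self_arc_and_unknown_id_rejected():
    records = [{"student": "a", "respondent": 1}, {"student": "b", "respondent": 1}]
    with pytest.raises(NetworkDataError, match="self-arc"):
        load_multilevel_network([("a", "a")], [], records)
    with pytest.raises(NetworkDataError, match="unknown student"):
        load_multilevel_network([("a", "zz")], [], records)
    with pytest.raises(NetworkDataError, match="unknown student"):
        load_multilevel_network([], [("zz", "g1")], records)


def test_duplicate_records_collapse_with_warning(caplog):
    records = [{"student": "a", "respondent": 1}, {"student": "b", "respondent": 1}]
    with caplog.at_level(logging.WARNING, logger="mergm.netdata"):
        net, _ = load_multilevel_network([("a", "b"), ("a", "b")], [], records)
    assert net.y.sum() == 1
    assert any("duplicate" in r.message for r in caplog.records)


def test_out_degree_cap_strict_vs_lenient():
    records = [{"student": f"s{i}", "respondent": 1} for i in range(5)]
    arcs = [("s0", f"s{j}") for j in range(1, 5)]
    with pytest.raises(NetworkDataError, match="cap"):
        load_multilevel_network(arcs, [], records, max_out=3, strict=True)
    net, _ = load_multilevel_network(arcs, [], records, max_out=3, strict=False)
    assert net.out_degrees()[0] == 3


@pytest.mark.parametrize("n,resp_idx,expected", [
    (10, None, 90),          # full response: n(n-1)
    (3, [0, 1], 4),          # one non-respondent: 2 * 2
    (1, None, 0),            # degenerate single node
])
def test_free_tie_variable_counts(n, resp_idx, expected):
    records = [{"student": f"s{i}",
                "respondent": int(resp_idx is None or i in resp_idx)}
               for i in range(n)]
    net, _ = load_multilevel_network([], [], records)
    free = free_tie_variables(net)
    assert len(free) == expected
    assert all(net.respondent[i] for i, _ in free)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(2, 12), st.integers(0, 2**31 - 1))
def test_free_set_size_identity(n, seed):
    """|free set| = sum over respondents of (n-1), on any loadable roster."""
    rng = np.random.default_rng(seed)
    resp = rng.random(n) < 0.7
    records = [{"student": f"s{i}", "respondent": int(resp[i])} for i in range(n)]
    net, _ = load_multilevel_network([], [], records)
    assert len(free_tie_variables(net)) == int(resp.sum()) * (n - 1)


def test_round_trip_is_exact(tmp_path, g3):
    net, attrs = g3
    p = {k: tmp_path / f"{k}.csv" for k in ("arcs", "aff", "attr")}
    write_school(net, attrs, p["arcs"], p["aff"], p["attr"])
    net2, attrs2 = read_school(p["arcs"], p["aff"], p["attr"])
    assert net2.students == net.students and net2.groups == net.groups
    assert np.array_equal(net2.y, net.y) and np.array_equal(net2.z, net.z)
    # second write reproduces the canonical files byte-for-byte
    q = {k: tmp_path / f"{k}2.csv" for k in p}
    write_school(net2, attrs2, q["arcs"], q["aff"], q["attr"])
    for k in p:
        assert p[k].read_bytes() == q[k].read_bytes()


def test_matrix_writer(tmp_path, g3):
    net, _ = g3
    write_matrices(net, tmp_path / "adj.txt", tmp_path / "inc.txt")
    adj = np.loadtxt(tmp_path / "adj.txt")
    inc = np.loadtxt(tmp_path / "inc.txt")
    assert np.array_equal(adj, net.y) and np.array_equal(inc, net.z)


def test_response_proportion_reported():
    records = [{"student": f"s{i}", "respondent": int(i < 79)} for i in range(100)]
    net, attrs = load_multilevel_network([], [], records)
    assert summarize(net, attrs)["response_proportion"] == pytest.approx(0.79)
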