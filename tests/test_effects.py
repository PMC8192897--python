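"""Statistic and change-statistic checks against independent oracles.

The alternating-star closed forms are validated against the explicit
alternating series over star counts; change statistics are validated
against brute-force full recounts of toggled networks.
"""

import numpy as np
import pytest
from scipy.special import comb

from mergm import (
    EffectTerm,
    ModelSpec,
    NetworkDataError,
    default_model_spec,
    free_tie_variables,
    statistics,
)
from mergm.effects import (
    Design,
    actor_relation_statistics,
    cross_level_statistics,
    structural_statistics,
)

from conftest import make_random_network


# -- hand-worked fixture values ---------------------------------------------

G3_EXPECTED = {
    "ArcA": 3.0, "ReciprocityA": 1.0, "AinSA": 0.0, "AoutSA": 1.0,
    "ATA-T": 0.0, "A2PA-T": 1.0,
    ("Sender", "knowledge"): 5.0, ("Receiver", "knowledge"): 7.0,
    ("Difference", "knowledge"): 4.0,
    ("Sender", "gender"): 1.0, ("Receiver", "gender"): 2.0,
    ("Interaction", "gender"): 0.0,
    "In2StarAX": 4.0, "Out2StarAX": 5.0, "TXAXarc": 3.0, "L3XAX": 3.0,
}


@pytest.mark.parametrize("key,expected", list(G3_EXPECTED.items()),
                         ids=lambda k: str(k))
def test_g3_fixture_statistics(g3, key, expected):
    net, attrs = g3
    name, attr = key if isinstance(key, tuple) else (key, None)
    term = EffectTerm(name, attr, 2.0)
    if name in ("ArcA", "ReciprocityA", "AinSA", "AoutSA", "ATA-T", "A2PA-T"):
        val = structural_statistics(net, [term])[0]
    elif name in ("In2StarAX", "Out2StarAX", "TXAXarc", "L3XAX"):
        val = cross_level_statistics(net, [term])[0]
    else:
        val = actor_relation_statistics(net, attrs, term)
    assert val == pytest.approx(expected, abs=1e-12)


# -- alternating-star series oracle -----------------------------------------

def alternating_star_series(degrees, lam):
    """Independent oracle: sum_k (-1)^k S_k / lam^(k-2) over star counts S_k."""
    degrees = np.asarray(degrees)
    total = 0.0
    for k in range(2, int(degrees.max(initial=0)) + 1):
        s_k = comb(degrees, k).sum()
        total += (-1) ** k * s_k / lam ** (k - 2)
    return total


@pytest.mark.parametrize("lam", [1.5, 2.0, 3.0])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_alternating_stars_match_series(lam, seed):
    net, _ = make_random_network(n=10, density=0.35, resp_p=1.0, seed=seed)
    ain, aout = structural_statistics(
        net, [EffectTerm("AinSA", lam=lam), EffectTerm("AoutSA", lam=lam)])
    assert ain == pytest.approx(alternating_star_series(net.in_degrees(), lam), abs=1e-9)
    assert aout == pytest.approx(alternating_star_series(net.out_degrees(), lam), abs=1e-9)


def test_path_closure_two_path_split():
    """ATA-T sums closed arcs only; A2PA-T sums every ordered two-path pair."""
    net, attrs = make_random_network(n=8, density=0.3, resp_p=1.0, seed=5)
    lam = 2.0
    r = 1 - 1 / lam
    y = net.y.astype(int)
    TP = y @ y
    ata = lam * sum((1 - r ** TP[i, j]) for i, j in zip(*np.nonzero(y)))
    a2pa = lam * sum((1 - r ** TP[i, j])
                     for i in range(8) for j in range(8) if i != j)
    got = structural_statistics(net, [EffectTerm("ATA-T", lam=lam),
                                      EffectTerm("A2PA-T", lam=lam)])
    assert got == pytest.approx([ata, a2pa], abs=1e-9)


# -- change statistics --------------------------------------------------------

def test_first_arc_change_on_empty_network(g3):
    net, attrs = g3
    net = net.copy()
    net.y[:] = 0
    spec = default_model_spec()
    d = Design(net, attrs, spec)
    dz = d.change_statistics((0, 1))
    assert dz[spec.index_of("ArcA")] == 1.0
    assert dz[spec.index_of("ReciprocityA")] == 0.0
    # first arc on an empty graph: degrees and two-paths are all zero, so the
    # alternating terms move by lam*(1 - r^0) = 0
    assert dz[spec.index_of("AinSA")] == 0.0
    assert dz[spec.index_of("AoutSA")] == 0.0
    assert dz[spec.index_of("ATA-T")] == 0.0
    assert dz[spec.index_of("A2PA-T")] == 0.0


def test_reciprocation_change(g3):
    net, attrs = g3
    y = net.y.copy()
    y[1, 0] = 0  # remove arc 2->1
    spec = ModelSpec([EffectTerm("ArcA"), EffectTerm("ReciprocityA")])
    d = Design(net, attrs, spec)
    dz = d.change_statistics((1, 0), y=y)
    assert dz[1] == 1.0  # toggling 2->1 on reciprocates 1->2


@pytest.mark.parametrize("seed", range(20))
def test_change_statistics_equal_recount(seed):
    """Incremental toggle differences equal z(on) - z(off) recounted in full."""
    net, attrs = make_random_network(n=6, m=2, seed=seed)
    d = Design(net, attrs, default_model_spec())
    for (i, j) in free_tie_variables(net):
        y_on = net.y.copy(); y_on[i, j] = 1
        y_off = net.y.copy(); y_off[i, j] = 0
        recount = d.statistics(y_on) - d.statistics(y_off)
        np.testing.assert_allclose(d.change_statistics((i, j)), recount, atol=1e-9)


def test_change_statistics_outside_free_set_rejected():
    net, attrs = make_random_network(n=5, resp_p=0.5, seed=3)
    d = Design(net, attrs, ModelSpec([EffectTerm("ArcA")]))
    nonresp = int(np.nonzero(~net.respondent)[0][0])
    with pytest.raises(NetworkDataError, match="free tie-variable"):
        d.change_statistics((nonresp, (nonresp + 1) % 5))
    with pytest.raises(NetworkDataError, match="free tie-variable"):
        d.change_statistics((1, 1))


def test_dyad_independent_terms_have_state_free_changes():
    """Actor-relation and cross-level deltas do not depend on the rest of y."""
    net, attrs = make_random_network(n=7, m=3, seed=11)
    spec = ModelSpec([EffectTerm("ArcA"), EffectTerm("Sender", "knowledge"),
                      EffectTerm("Receiver", "gender"), EffectTerm("Interaction", "gender"),
                      EffectTerm("Difference", "talking"), EffectTerm("PSTalkingSender"),
                      EffectTerm("In2StarAX"), EffectTerm("Out2StarAX"),
                      EffectTerm("TXAXarc"), EffectTerm("L3XAX")])
    d = Design(net, attrs, spec)
    rng = np.random.default_rng(0)
    pairs = list(free_tie_variables(net))
    for (i, j) in pairs[:10]:
        ref = d.change_statistics((i, j), y=np.zeros_like(net.y))
        for _ in range(5):
            y = (rng.random(net.y.shape) < 0.4).astype(np.int8)
            np.fill_diagonal(y, 0)
            y[~net.respondent] = 0
            np.testing.assert_allclose(d.change_statistics((i, j), y=y), ref, atol=1e-12)


# -- invariances --------------------------------------------------------------

def test_permutation_invariance():
    net, attrs = make_random_network(n=8, m=2, seed=21)
    spec = default_model_spec()
    base = statistics(net, attrs, spec)
    rng = np.random.default_rng(1)
    perm = rng.permutation(net.n)
    from mergm import AttributeTable, MultilevelNetwork
    net_p = MultilevelNetwork(
        [net.students[i] for i in perm], list(net.groups),
        net.y[np.ix_(perm, perm)], net.z[perm], net.respondent[perm], net.max_out)
    attrs_p = AttributeTable(attrs.frame.iloc[perm])
    np.testing.assert_allclose(statistics(net_p, attrs_p, spec), base, atol=1e-9)


def test_empty_graph_statistics_are_zero():
    net, attrs = make_random_network(n=6, seed=2)
    net.y[:] = 0
    np.testing.assert_allclose(statistics(net, attrs, default_model_spec()),
                               0.0, atol=1e-12)


# -- term validation ----------------------------------------------------------

def test_term_validation_rules():
    with pytest.raises(NetworkDataError):
        EffectTerm("Sender")                    # missing attribute
    with pytest.raises(NetworkDataError):
        EffectTerm("Interaction", "knowledge")  # continuous homophily -> Difference
    with pytest.raises(NetworkDataError):
        EffectTerm("Difference", "gender")      # binary difference undefined
    with pytest.raises(NetworkDataError):
        EffectTerm("ArcA", lam=0.5)             # lambda below 1
    with pytest.raises(NetworkDataError):
        ModelSpec([EffectTerm("ReciprocityA")])  # no density term
    with pytest.raises(NetworkDataError):
        ModelSpec([EffectTerm("ArcA"), EffectTerm("ArcA")])


def test_model_spec_yaml_round_trip():
    spec = default_model_spec()
    again = ModelSpec.from_yaml(spec.to_yaml())
    assert again.labels == spec.labels
    assert [t.lam for t in again.terms] == [t.lam for t in spec.terms]
    assert again.condition_max_out == spec.condition_max_out


def test_default_spec_has_26_reporting_rows():
    spec = default_model_spec()
    assert len(spec) == 26
    assert spec.labels[:6] == ["ArcA", "ReciprocityA", "AinSA", "AoutSA", "ATA-T", "A2PA-T"]
    assert "PS Talking-Sender" in spec.labels and "TXAXarc" in spec.labels
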