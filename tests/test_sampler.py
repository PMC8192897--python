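"""Sampler checks: closed-form Bernoulli limits, constraint conservation,
seed determinism, and exact-distribution agreement on an enumerable space."""

import numpy as np
import pytest

from mergm import (
    EffectTerm,
    ModelSpec,
    MultilevelNetwork,
    SamplerConfig,
    free_tie_variables,
    simulate,
)
from mergm.effects import Design
from mergm.sampler import SamplerError, metropolis_step, new_chain

from conftest import assert_constraints, make_random_network


def bernoulli_net(n, seed=0):
    net, attrs = make_random_network(n=n, m=0, density=0.0, resp_p=1.0, seed=seed)
    return net, attrs


def test_density_only_theta_zero_gives_half():
    """theta = 0, no constraints: every free dyad is an independent fair coin."""
    net, _ = bernoulli_net(12)
    cfg = SamplerConfig(seed=1, n_samples=400, burn_in=5_000, thinning=264,
                        respect_max_out=False, start="empty")
    batch = simulate(net, [0.0], ModelSpec([EffectTerm("ArcA")], condition_max_out=False), cfg)
    free = len(free_tie_variables(net))
    dens = batch.stats[:, 0] / free
    mc_se = dens.std(ddof=1) / np.sqrt(len(dens))
    assert abs(dens.mean() - 0.5) < 3 * mc_se + 1e-3


def test_density_only_theta_minus_one_matches_logistic():
    net, _ = bernoulli_net(12)
    cfg = SamplerConfig(seed=2, n_samples=400, burn_in=5_000, thinning=264,
                        respect_max_out=False, start="empty")
    batch = simulate(net, [-1.0], ModelSpec([EffectTerm("ArcA")], condition_max_out=False), cfg)
    free = len(free_tie_variables(net))
    dens = batch.stats[:, 0] / free
    mc_se = dens.std(ddof=1) / np.sqrt(len(dens))
    assert abs(dens.mean() - 1 / (1 + np.e)) < 3 * mc_se + 1e-3


def test_out_degree_cap_and_structural_zeros_conserved():
    net, attrs = make_random_network(n=10, m=2, density=0.3, resp_p=0.7, seed=5)
    cfg = SamplerConfig(seed=3, n_samples=80, burn_in=3_000, thinning=200,
                        keep_networks=True)
    # strongly positive density pushes against the cap
    batch = simulate(net, [1.5], ModelSpec([EffectTerm("ArcA")]), cfg, attrs)
    for ys in batch.networks:
        assert_constraints(ys, net)
    # with the cap active and density pushed up, respondents saturate at the cap
    assert max(ys[net.respondent].sum(axis=1).max() for ys in batch.networks) == net.max_out


def test_cap_rejection_is_immediate():
    """A proposal that would create a seventh nomination is never accepted."""
    n = 9
    y = np.zeros((n, n), np.int8)
    y[0, 1:7] = 1  # sender 0 at the cap
    net = MultilevelNetwork([f"s{i}" for i in range(n)], [], y,
                            np.zeros((n, 0), np.int8), np.ones(n, bool), max_out=6)
    spec = ModelSpec([EffectTerm("ArcA")], condition_max_out=True)
    chain = new_chain(net, [10.0], spec, SamplerConfig(seed=0, start="observed"))
    chain.advance(20_000)
    assert chain.dout[0] <= 6
    chain.verify_state()


def test_seed_determinism_bit_for_bit():
    net, attrs = make_random_network(n=8, m=2, seed=7)
    spec = ModelSpec([EffectTerm("ArcA"), EffectTerm("ReciprocityA")])
    cfg = SamplerConfig(seed=99, n_samples=50, burn_in=1_000, thinning=100,
                        keep_networks=True)
    b1 = simulate(net, [-1.0, 0.5], spec, cfg, attrs)
    b2 = simulate(net, [-1.0, 0.5], spec, cfg, attrs)
    assert np.array_equal(b1.stats, b2.stats)
    assert all(np.array_equal(a, b) for a, b in zip(b1.networks, b2.networks))
    assert b1.acceptance_rate == b2.acceptance_rate


def test_theta_length_mismatch_rejected():
    net, attrs = make_random_network(n=5, seed=1)
    spec = ModelSpec([EffectTerm("ArcA"), EffectTerm("ReciprocityA")])
    with pytest.raises(SamplerError, match="theta length"):
        simulate(net, [0.0], spec, SamplerConfig(seed=1, n_samples=1,
                                                 burn_in=10, thinning=10), attrs)


def test_nonpositive_config_rejected():
    net, attrs = make_random_network(n=5, seed=1)
    spec = ModelSpec([EffectTerm("ArcA")])
    with pytest.raises(SamplerError):
        simulate(net, [0.0], spec, SamplerConfig(seed=1, n_samples=0), attrs)
    with pytest.raises(SamplerError):
        simulate(net, [0.0], spec, SamplerConfig(seed=1, thinning=0), attrs)


def test_zero_change_proposal_always_accepted(g3):
    """theta.dz = 0 gives acceptance probability 1 for every proposal."""
    net, attrs = g3
    spec = ModelSpec([EffectTerm("ArcA")], condition_max_out=False)
    chain = new_chain(net, [0.0], spec, SamplerConfig(seed=12, start="empty"))
    metropolis_step(chain)
    assert chain.accepted == chain.proposed == 1
    chain.advance(999)
    assert chain.accepted == chain.proposed == 1000


def test_exact_gibbs_distribution_on_enumerable_space():
    """Long-run state frequencies match exhaustive enumeration (TV < 0.02).

    Four students, two respondents: a 6-dyad free space with 64 states,
    model {ArcA, ReciprocityA}. Shorter companion to the full-length run in
    the acceptance suite.
    """
    resp = np.array([True, True, False, False])
    net = MultilevelNetwork(list("abcd"), [], np.zeros((4, 4), np.int8),
                            np.zeros((4, 0), np.int8), resp, max_out=6)
    spec = ModelSpec([EffectTerm("ArcA"), EffectTerm("ReciprocityA")],
                     condition_max_out=False)
    design = Design(net, None, spec)
    pairs = list(free_tie_variables(net))
    theta = np.array([-0.6, 0.8])

    logw = np.empty(64)
    for code in range(64):
        y = np.zeros((4, 4), np.int8)
        for b, (i, j) in enumerate(pairs):
            if code >> b & 1:
                y[i, j] = 1
        logw[code] = theta @ design.statistics(y)
    p = np.exp(logw - logw.max())
    p /= p.sum()

    chain = new_chain(net, theta, design, SamplerConfig(seed=123, start="empty"))
    chain.enable_recording()
    rec = np.empty(400_000, dtype=np.int64)
    chain.advance(rec.size, record=rec)
    phat = np.bincount(rec, minlength=64) / rec.size
    assert 0.5 * np.abs(phat - p).sum() < 0.02
    chain.verify_state()
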