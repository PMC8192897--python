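"""Metropolis simulation of friendship networks at fixed affiliations.

The chain proposes a uniform toggle of one free tie variable (respondent
sender, any distinct receiver) and accepts with probability
min(1, exp(θ·Δz)).  When out-degree conditioning is on, proposals that would
push a respondent past the nomination cap are rejected outright, which is
Metropolis on the cap-constrained sample space.  Structural zeros are
conserved by construction: dyads outside the free set are never proposed.

Retained statistics are *recounted in full* at every sample point from the
current adjacency; the incremental change statistics drive only the
accept/reject decisions, and the incrementally maintained two-path matrix is
cross-checked against an exact recount at regular intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _mcmc
from .effects import Design, ModelSpec
from .netdata import AttributeTable, MultilevelNetwork, NetworkDataError

_CHUNK = 200_000  # proposals pre-drawn per kernel call


class SamplerError(ValueError):
    pass


@dataclass
class SamplerConfig:
    """Chain-length and conditioning knobs.  ``seed`` is mandatory.

    ``burn_in`` and ``thinning`` default to 50x and 10x the number of free
    tie variables — a rule of thumb scaling with the state-space size.
    ``respect_max_out=None`` follows the model's conditioning flag.
    """

    seed: int
    burn_in: int | None = None
    thinning: int | None = None
    n_samples: int = 100
    respect_max_out: bool | None = None
    start: str = "observed"  # or "empty"
    keep_networks: bool = False
    recount_every: int = 50

    def resolved(self, free_count: int) -> tuple[int, int]:
        burn = 50 * free_count if self.burn_in is None else self.burn_in
        thin = 10 * free_count if self.thinning is None else self.thinning
        if burn < 0 or thin <= 0 or self.n_samples <= 0:
            raise SamplerError("burn_in must be >= 0; thinning and n_samples positive")
        return burn, thin


@dataclass
class SampleBatch:
    """Simulated statistic vectors plus chain bookkeeping."""

    stats: np.ndarray          # (n_samples, n_terms)
    acceptance_rate: float
    labels: list[str]
    networks: list[np.ndarray] | None = None
    final_y: np.ndarray | None = None


class _Chain:
    """A running chain over one design; advances in pre-drawn proposal chunks."""

    def __init__(self, design: Design, theta: np.ndarray, seed,
                 respect_cap: bool, y0: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(design.codes),):
            raise SamplerError(
                f"theta length {theta.size} does not match model with {len(design.codes)} terms")
        if design.senders.size == 0:
            raise SamplerError("no free tie variables: every student is a non-respondent")
        self.design = design
        self.theta = theta
        self.rng = np.random.default_rng(seed)
        self.respect_cap = bool(respect_cap)
        self.y, self.TP, self.din, self.dout = design.make_state(y0)
        if self.respect_cap and (self.dout[design.senders] > design.max_out).any():
            raise SamplerError("start state violates the out-degree cap")
        self.proposed = 0
        self.accepted = 0
        self._bits = np.full((design.net.n, design.net.n), -1, dtype=np.int64)
        self._code = np.int64(0)
        self._norec = np.empty(0, dtype=np.int64)

    def set_theta(self, theta: np.ndarray) -> None:
        self.theta = np.asarray(theta, dtype=float)

    def advance(self, steps: int, record: np.ndarray | None = None) -> None:
        d = self.design
        n = d.net.n
        done = 0
        while done < steps:
            m = min(_CHUNK, steps - done)
            si = self.rng.integers(0, d.senders.size, m)
            jo = self.rng.integers(0, n - 1, m)
            uu = self.rng.random(m)
            rec = self._norec if record is None else record[done:done + m]
            acc, self._code = _mcmc.run_chain(
                self.y, self.TP, self.din, self.dout, d.D, d.codes, d.lams,
                self.theta, d.senders, d.max_out, self.respect_cap,
                si, jo, uu, rec, self._bits, self._code)
            self.accepted += int(acc)
            self.proposed += m
            done += m

    def statistics(self) -> np.ndarray:
        return self.design.statistics_from_state(self.y, self.TP)

    def verify_state(self) -> None:
        """Cross-check the incrementally maintained two-path matrix and degrees."""
        yi = self.y.astype(np.int32)
        if not np.array_equal(self.TP, yi @ yi):
            raise SamplerError("incremental two-path state diverged from full recount")
        if not np.array_equal(self.din, yi.sum(axis=0)) or \
           not np.array_equal(self.dout, yi.sum(axis=1)):
            raise SamplerError("incremental degree state diverged from full recount")

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0

    # bit-coded state recording on desk-scale spaces -----------------------
    def enable_recording(self) -> list[tuple[int, int]]:
        """Assign one bit per free dyad (sender-major order); ≤ 63 dyads."""
        from .netdata import free_tie_variables
        pairs = list(free_tie_variables(self.design.net))
        if len(pairs) > 63:
            raise SamplerError("state recording supports at most 63 free dyads")
        for b, (i, j) in enumerate(pairs):
            self._bits[i, j] = b
        code = 0
        for b, (i, j) in enumerate(pairs):
            if self.y[i, j]:
                code |= 1 << b
        self._code = np.int64(code)
        return pairs


def _resolve_design(net_template, spec, attrs):
    if isinstance(spec, Design):
        return spec
    return Design(net_template, attrs, spec)


def metropolis_step(state: _Chain, theta: np.ndarray | None = None) -> _Chain:
    """Advance a chain by a single proposal (convenience for desk checks)."""
    if theta is not None:
        state.set_theta(theta)
    state.advance(1)
    return state


def new_chain(net_template: MultilevelNetwork, theta, spec: ModelSpec | Design,
              config: SamplerConfig, attrs: AttributeTable | None = None) -> _Chain:
    design = _resolve_design(net_template, spec, attrs)
    respect = (design.spec.condition_max_out if config.respect_max_out is None
               else config.respect_max_out)
    y0 = design.net.y if config.start == "observed" else None
    return _Chain(design, np.asarray(theta, float), config.seed, respect, y0)


def simulate(net_template: MultilevelNetwork, theta, spec: ModelSpec | Design,
             config: SamplerConfig, attrs: AttributeTable | None = None) -> SampleBatch:
    """Draw ``config.n_samples`` networks from the model at ``theta``.

    Reproducible bit-for-bit for a given seed.  Statistic rows are full
    recounts at each retained sample.
    """
    design = _resolve_design(net_template, spec, attrs)
    burn, thin = config.resolved(design.free_count)
    chain = new_chain(net_template, theta, design, config, attrs)
    chain.advance(burn)
    k = len(design.codes)
    stats = np.empty((config.n_samples, k))
    nets = [] if config.keep_networks else None
    for s in range(config.n_samples):
        chain.advance(thin)
        stats[s] = chain.statistics()
        if nets is not None:
            nets.append(chain.y.copy())
        if config.recount_every and (s + 1) % config.recount_every == 0:
            chain.verify_state()
    chain.verify_state()
    return SampleBatch(stats, chain.acceptance_rate, design.labels,
                       networks=nets, final_y=chain.y.copy())


def export_trace(batch: SampleBatch, path) -> None:
    """Write the statistic trace as delimited text for external diagnostics."""
    import pandas as pd
    pd.DataFrame(batch.stats, columns=batch.labels).to_csv(path, index=False)
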