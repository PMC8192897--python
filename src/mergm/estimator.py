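"""Monte-Carlo maximum likelihood for the multilevel friendship model.

For an exponential-family network model P(y) ∝ exp(θ·z(y)) the MLE solves
the moment equation E_θ[z(Y)] = z_obs.  The expectation has no closed form,
so it is approximated by MCMC simulation and the equation is solved by
three-phase stochastic approximation (Robbins–Monro):

* **Phase 1** — a short simulation at the crude starting point θ₀ (logit of
  observed density on the density term, zeros elsewhere) estimates the
  per-term statistic variances used as a diagonal scaling D.
* **Phase 2** — subphases of Robbins–Monro iterations
  θ ← θ − a·D⁻¹·(z_sim − z_obs) with the gain ``a`` halved between
  subphases and subphase length doubled; θ̂ is the iterate average over the
  final subphase.
* **Phase 3** — a long simulation at θ̂ yields the convergence t-ratios
  t_k = (mean z_sim,k − z_obs,k)/sd(z_sim,k), the statistic covariance Σ̂,
  and standard errors sqrt(diag(Σ̂⁻¹)) (the Fisher-information
  approximation).  If any |t_k| exceeds the convergence threshold, θ̂ is
  polished with damped Newton steps θ ← θ − Σ̂⁻¹(mean z_sim − z_obs) and
  phase 3 is repeated, up to a bounded number of rounds.

A parameter is reported significant when its magnitude reaches twice its
standard error.  Published tables round to three decimals, where a true
ratio just above 2 can print as exactly 2.0; the threshold comparison is
therefore inclusive (``|θ| ≥ 2·SE``), which is indistinguishable from the
strict rule for full-precision estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .effects import Design, ModelSpec
from .netdata import AttributeTable, MultilevelNetwork
from .sampler import SamplerConfig, _Chain, new_chain

logger = logging.getLogger(__name__)

# statistics that are non-negative and only zero on boundary configurations:
# an observed zero puts the MLE at -infinity for that term
_NONNEGATIVE_ZERO_BOUNDARY = {
    "ReciprocityA", "ATA-T", "A2PA-T", "TXAXarc", "L3XAX", "In2StarAX", "Out2StarAX",
}


class EstimationError(RuntimeError):
    pass


class BoundaryError(EstimationError):
    """Observed statistic at the edge of its range: the MLE does not exist."""


class DegeneracyError(EstimationError):
    """Simulated networks collapsed to (near-)empty or complete graphs."""


class CollinearityError(EstimationError):
    """Change-statistic columns linearly dependent on the observed network."""


@dataclass
class EstimationConfig:
    """Stochastic-approximation settings; every default is overridable.

    Chain lengths are expressed as multiples of the free tie-variable count
    so the same configuration scales across school sizes.
    """

    seed: int
    phase1_samples: int = 100
    subphases: int = 5
    subphase_base: int = 40          # iterations in first subphase, doubling
    a0: float = 0.1                  # initial Robbins-Monro gain
    phase3_samples: int = 1500
    conv_threshold: float = 0.1
    max_newton_rounds: int = 6
    burn_mult: float = 10.0          # burn-in, x free tie variables
    thin_mult: float = 1.0           # thinning, x free tie variables
    steps_per_iter_mult: float = 0.25
    max_step: float = 0.5            # per-component cap on phase-2 updates
    probe_dyads: int = 1000          # collinearity probe sample

    def __post_init__(self):
        if self.conv_threshold <= 0:
            raise ValueError("convergence threshold must be positive")
        for name in ("phase1_samples", "subphases", "subphase_base", "phase3_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics for one fitted school model."""

    labels: list[str]
    theta: np.ndarray
    se: np.ndarray
    conv_t: np.ndarray
    significant: np.ndarray
    stat_cov: np.ndarray
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "effect": self.labels,
            "parameter": self.theta,
            "stderr": self.se,
            "conv_t": self.conv_t,
            "significant": self.significant,
        })

    def to_table(self) -> str:
        """Delimited table: effect, parameter, stderr, significance marker."""
        lines = ["effect\tparameter\tstderr\tsignificant"]
        for lab, th, se, sig in zip(self.labels, self.theta, self.se, self.significant):
            lines.append(f"{lab}\t{th:.3f}\t{se:.3f}\t{'*' if sig else ''}")
        return "\n".join(lines)


def significance(theta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided flag: |θ_k| at least twice the standard error.

    Inclusive at the boundary so that three-decimal published pairs whose
    unrounded ratio exceeded 2 (printing as exactly 2.0) are reproduced; for
    full-precision estimates the boundary has probability zero.
    """
    theta = np.asarray(theta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return np.abs(theta) >= 2.0 * se


def standard_errors(stat_cov: np.ndarray) -> tuple[np.ndarray, bool]:
    """SEs from the inverse simulated-statistic covariance at θ̂.

    Returns ``(se, used_pseudoinverse)``; near-singular covariances fall back
    to the Moore-Penrose pseudo-inverse with a logged warning.
    """
    cov = np.asarray(stat_cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("statistic covariance near-singular (cond=%.2e); using pseudo-inverse", cond)
        inv = np.linalg.pinv(cov)
        return np.sqrt(np.clip(np.diag(inv), 0.0, None)), True
    inv = np.linalg.inv(cov)
    return np.sqrt(np.clip(np.diag(inv), 0.0, None)), False


def _check_boundaries(design: Design, z_obs: np.ndarray) -> None:
    free = design.free_count
    if free == 0:
        raise BoundaryError("no free tie variables to model")
    t_arc = [k for k, term in enumerate(design.spec.terms) if term.name == "ArcA"]
    if t_arc:
        arcs = z_obs[t_arc[0]]
        if arcs <= 0:
            raise BoundaryError(
                "observed network is empty: the density MLE is -infinity")
        if arcs >= free:
            raise BoundaryError(
                "observed network is complete on the free set: density MLE is +infinity")
    for k, term in enumerate(design.spec.terms):
        if term.name in _NONNEGATIVE_ZERO_BOUNDARY and z_obs[k] == 0:
            raise BoundaryError(
                f"observed statistic for {term.label} is 0, its minimum: the MLE sits on "
                "the boundary — remove the term or use a richer network")


def _check_collinearity(design: Design, config: EstimationConfig) -> None:
    from .netdata import free_tie_variables
    pairs = list(free_tie_variables(design.net))
    rng = np.random.default_rng(int(config.seed) + 101)
    if len(pairs) > config.probe_dyads:
        idx = rng.choice(len(pairs), size=config.probe_dyads, replace=False)
        pairs = [pairs[i] for i in idx]
    X = np.array([design.change_statistics(p) for p in pairs])
    if np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, float(np.abs(X).max()))) < X.shape[1]:
        raise CollinearityError(
            "change-statistic columns are linearly dependent on the observed network; "
            "drop redundant terms before fitting")


def _theta0(design: Design, z_obs: np.ndarray) -> np.ndarray:
    theta = np.zeros(len(design.codes))
    for k, term in enumerate(design.spec.terms):
        if term.name == "ArcA":
            d = np.clip(z_obs[k] / design.free_count, 1e-4, 1 - 1e-4)
            theta[k] = float(np.log(d / (1 - d)))
    return theta


def _phase_chain(design: Design, theta, seed: int, config: EstimationConfig) -> _Chain:
    scfg = SamplerConfig(seed=seed, start="observed")
    return new_chain(design.net, theta, design, scfg)


def fit_mergm(net: MultilevelNetwork, attrs: AttributeTable | None, spec: ModelSpec,
              config: EstimationConfig) -> FitResult:
    """Three-phase MCMC maximum-likelihood fit of ``spec`` to one school."""
    design = Design(net, attrs, spec)
    z_obs = design.statistics()
    if not np.all(np.isfinite(z_obs)):
        raise EstimationError("observed statistics are not finite")
    _check_boundaries(design, z_obs)
    _check_collinearity(design, config)

    free = design.free_count
    burn = max(1, int(config.burn_mult * free))
    thin = max(1, int(config.thin_mult * free))
    steps_per_iter = max(50, int(config.steps_per_iter_mult * free))
    k = len(design.codes)
    warnings_log: list[str] = []

    # ---- phase 1: diagonal scaling ---------------------------------------
    theta = _theta0(design, z_obs)
    chain = _phase_chain(design, theta, int(config.seed), config)
    chain.advance(burn)
    p1 = np.empty((config.phase1_samples, k))
    for s in range(config.phase1_samples):
        chain.advance(thin)
        p1[s] = chain.statistics()
    D = p1.var(axis=0, ddof=1)
    dead = D <= 1e-12
    if dead.any():
        names = [design.labels[i] for i in np.nonzero(dead)[0]]
        raise DegeneracyError(
            f"simulated statistics constant at theta0 for terms {names}: "
            "the chain is stuck (degenerate or boundary model)")

    # ---- phase 2: Robbins-Monro subphases --------------------------------
    chain.verify_state()
    theta_hat = theta.copy()
    iters_total = 0
    for sub in range(config.subphases):
        a = config.a0 / (2 ** sub)
        iters = config.subphase_base * (2 ** sub)
        acc = np.zeros(k)
        stuck = 0
        for _ in range(iters):
            chain.advance(steps_per_iter)
            z_sim = chain.statistics()
            step = a * (z_sim - z_obs) / D
            np.clip(step, -config.max_step, config.max_step, out=step)
            theta -= step
            chain.set_theta(theta)
            acc += theta
            arcs = float(chain.y.sum())
            if arcs <= 0 or arcs >= free:
                stuck += 1
        iters_total += iters
        if stuck > iters // 2:
            raise DegeneracyError(
                "chain spent most of a subphase on empty/complete graphs; "
                "the model is degenerate at the current estimate")
        theta_hat = acc / iters
    theta = theta_hat
    chain.verify_state()

    # ---- phase 3: convergence check, covariance, SEs ---------------------
    used_pinv = False
    for round_ in range(config.max_newton_rounds + 1):
        chain = _phase_chain(design, theta, int(config.seed) + 7919 * (round_ + 1), config)
        chain.advance(burn)
        p3 = np.empty((config.phase3_samples, k))
        for s in range(config.phase3_samples):
            chain.advance(thin)
            p3[s] = chain.statistics()
        chain.verify_state()
        mean = p3.mean(axis=0)
        sd = p3.std(axis=0, ddof=1)
        if np.any(sd <= 1e-12):
            raise DegeneracyError("phase-3 statistics collapsed to a point")
        conv_t = (mean - z_obs) / sd
        cov = np.cov(p3, rowvar=False).reshape(k, k)
        if np.all(np.abs(conv_t) < config.conv_threshold) or round_ == config.max_newton_rounds:
            break
        # damped Newton polish on the moment equation, then re-check
        try:
            step = np.linalg.solve(cov, mean - z_obs)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(cov) @ (mean - z_obs)
            used_pinv = True
        norm = float(np.abs(step).max())
        if norm > 2 * config.max_step:
            step *= 2 * config.max_step / norm
        theta = theta - step

    se, pinv_flag = standard_errors(cov)
    used_pinv = used_pinv or pinv_flag
    if used_pinv:
        warnings_log.append("pseudo-inverse used for a near-singular statistic covariance")
    converged = bool(np.all(np.abs(conv_t) < config.conv_threshold))
    if not converged:
        warnings_log.append(
            f"not converged: max |t| = {np.abs(conv_t).max():.3f} "
            f"(threshold {config.conv_threshold})")
    sig = significance(theta, np.where(se > 0, se, np.inf))
    return FitResult(
        labels=list(design.labels),
        theta=theta,
        se=se,
        conv_t=conv_t,
        significant=sig,
        stat_cov=cov,
        converged=converged,
        diagnostics={
            "seed": int(config.seed),
            "phase2_iterations": iters_total,
            "newton_rounds": round_,
            "acceptance_rate": chain.acceptance_rate,
            "phase3_stats": p3,
            "z_obs": z_obs,
            "warnings": warnings_log,
        },
    )
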