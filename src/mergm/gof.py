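"""Goodness of fit: observed vs simulated statistics at the fitted parameters.

Networks are simulated from the fitted model and each statistic — the fitted
terms plus auxiliary descriptors that are *not* in the model — is compared
with its observed value through the t-ratio

    t = (observed − simulated mean) / simulated sd.

Fitted statistics were matched by estimation, so adequacy demands |t| below
the convergence threshold (0.1); auxiliary statistics only need |t| < 2.
The auxiliary panel covers the spread and skew of both degree
distributions, global transitivity, isolate and mutual-dyad counts — a
stand-in for the original study's unpublished panel, and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .effects import Design, ModelSpec
from .estimator import EstimationError, FitResult
from .netdata import AttributeTable, MultilevelNetwork
from .sampler import SamplerConfig, simulate


def _degree_sd(d: np.ndarray) -> float:
    return float(d.std(ddof=0)) if d.size else 0.0


def _degree_skew(d: np.ndarray) -> float:
    if d.size == 0 or d.std(ddof=0) <= 0:
        return 0.0
    return float(sps.skew(d))


def _transitivity(y: np.ndarray) -> float:
    """Fraction of directed two-paths i→k→j closed by an arc i→j."""
    yi = y.astype(np.int64)
    TP = yi @ yi
    denom = TP.sum() - np.trace(TP)
    if denom == 0:
        return 0.0
    closed = (yi * TP).sum()
    return float(closed / denom)


AUX_STATISTICS = {
    "indegree sd": lambda y: _degree_sd(y.sum(axis=0)),
    "indegree skew": lambda y: _degree_skew(y.sum(axis=0)),
    "outdegree sd": lambda y: _degree_sd(y.sum(axis=1)),
    "outdegree skew": lambda y: _degree_skew(y.sum(axis=1)),
    "transitivity": _transitivity,
    "isolates": lambda y: float(((y.sum(axis=0) + y.sum(axis=1)) == 0).sum()),
    "mutual dyads": lambda y: float((y * y.T).sum()) / 2.0,
}


@dataclass
class GOFReport:
    """Per-statistic comparison table with adequacy flags."""

    table: pd.DataFrame  # statistic, observed, sim_mean, sim_sd, t, fitted, adequate
    n_samples: int
    seed: int

    def to_text(self) -> str:
        lines = [f"Goodness of fit ({self.n_samples} simulated networks, seed {self.seed})",
                 f"{'statistic':<24}{'observed':>12}{'sim mean':>12}"
                 f"{'sim sd':>10}{'t':>9}  {'kind':<10}{'adequate'}"]
        for _, r in self.table.iterrows():
            kind = "fitted" if r["fitted"] else "auxiliary"
            tstr = f"{r['t']:9.3f}" if np.isfinite(r["t"]) else "      inf"
            lines.append(
                f"{r['statistic']:<24}{r['observed']:>12.3f}{r['sim_mean']:>12.3f}"
                f"{r['sim_sd']:>10.3f}{tstr}  {kind:<10}{'yes' if r['adequate'] else 'NO'}")
        return "\n".join(lines)

    @property
    def adequate(self) -> bool:
        return bool(self.table["adequate"].all())


def _t_ratio(obs: float, mean: float, sd: float) -> float:
    if sd > 0:
        return (obs - mean) / sd
    return 0.0 if obs == mean else np.inf


def goodness_of_fit(net: MultilevelNetwork, attrs: AttributeTable | None,
                    fit: FitResult, spec: ModelSpec, *,
                    aux: dict | None = None,
                    n_samples: int = 500, seed: int | None = None,
                    fitted_threshold: float = 0.1, aux_threshold: float = 2.0,
                    reuse_phase3: bool = False,
                    allow_nonconverged: bool = False) -> GOFReport:
    """Simulate at θ̂ and tabulate t-ratios for fitted and auxiliary statistics.

    With ``reuse_phase3=True`` the estimator's own phase-3 sample is reused
    for the fitted terms, so their t-ratios equal the convergence t-ratios
    exactly (no auxiliary panel in that mode unless networks are resimulated).
    """
    if not fit.converged and not allow_nonconverged:
        raise EstimationError(
            "refusing goodness of fit on a non-converged fit "
            "(pass allow_nonconverged=True to override)")
    aux = AUX_STATISTICS if aux is None else aux
    seed = int(fit.diagnostics.get("seed", 0)) + 40_009 if seed is None else int(seed)

    rows = []
    if reuse_phase3:
        # the estimator's own sample: needs no fresh simulation or network
        z_obs = np.asarray(fit.diagnostics["z_obs"])
        p3 = np.asarray(fit.diagnostics["phase3_stats"])
        mean, sd = p3.mean(axis=0), p3.std(axis=0, ddof=1)
        for k, lab in enumerate(fit.labels):
            t = _t_ratio(z_obs[k], mean[k], sd[k])
            rows.append((lab, z_obs[k], mean[k], sd[k], t, True,
                         bool(abs(t) < fitted_threshold)))
        n_used = p3.shape[0]
    else:
        design = Design(net, attrs, spec)
        z_obs = design.statistics()
        cfg = SamplerConfig(seed=seed, n_samples=n_samples, keep_networks=True,
                            burn_in=None, thinning=None)
        batch = simulate(net, fit.theta, design, cfg, attrs)
        mean, sd = batch.stats.mean(axis=0), batch.stats.std(axis=0, ddof=1)
        for k, lab in enumerate(fit.labels):
            t = _t_ratio(z_obs[k], mean[k], sd[k])
            rows.append((lab, z_obs[k], mean[k], sd[k], t, True,
                         bool(abs(t) < fitted_threshold)))
        yobs = net.y
        for name, fn in aux.items():
            obs = float(fn(yobs))
            sims = np.array([fn(ys) for ys in batch.networks])
            m, s = float(sims.mean()), float(sims.std(ddof=1))
            t = _t_ratio(obs, m, s)
            rows.append((name, obs, m, s, t, False, bool(abs(t) < aux_threshold)))
        n_used = n_samples

    table = pd.DataFrame(rows, columns=["statistic", "observed", "sim_mean",
                                        "sim_sd", "t", "fitted", "adequate"])
    return GOFReport(table=table, n_samples=n_used, seed=seed)
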