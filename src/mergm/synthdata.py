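"""Synthetic multilevel school networks.

The study's survey data are not deposited, so this module generates schools
with the same observable structure: a year group of students nominating up
to six close friends (directed arcs), peer supporters (PS) chosen from the
most-nominated quartile with partial uptake, PS-created online groups whose
membership aligns with offline friendship, and a response process that
removes the outgoing ties of non-respondents (structural zeros) while
keeping nominations they received.

Defaults mirror the study conditions: ~130 students per school, 79%
response, a cap of six nominations, the top 25% nominated invited with 52%
uptake (≈13% of the year group become PS).  Attribute scales are plausible
questionnaire scores (the study's own school-level tables are unpublished).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .netdata import (
    AttributeTable,
    MultilevelNetwork,
    load_multilevel_network,
)
from .sampler import SamplerConfig, simulate


@dataclass
class SchoolSimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int
    n_students: int = 130
    response_rate: float = 0.79
    male_proportion: float = 0.45
    nomination_cap: int = 6
    mean_nominations: float = 4.0     # mean out-degree target before capping
    ps_top_fraction: float = 0.25
    ps_uptake: float = 0.52
    groups_per_ps: int = 1
    baseline_join: float = 0.05       # group-join probability for non-friends
    affiliation_alignment: float = 8.0  # multiplier on baseline for friends of the PS
    # attribute model: multivariate normal scores with common correlation
    attr_means: tuple = (6.0, 7.0, 4.0)       # knowledge, norms, talking
    attr_sds: tuple = (1.5, 1.2, 1.8)
    attr_correlation: float = 0.3
    # friendship homophily / clustering strengths (log-odds scale)
    gender_match: float = 1.2
    distance_decay: float = 0.3       # per unit of summed |attribute difference|
    reciprocity_bonus: float = 1.5
    transitivity_bonus: float = 0.6   # per common friend, saturating at 3

    def __post_init__(self):
        for p in ("response_rate", "male_proportion", "ps_top_fraction",
                  "ps_uptake", "baseline_join"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be a probability")
        if self.n_students < 2:
            raise ValueError("need at least two students")
        if self.nomination_cap < 1:
            raise ValueError("nomination cap must be at least 1")
        if self.groups_per_ps < 1:
            raise ValueError("each peer supporter opens at least one group")


def generate_school(config: SchoolSimConfig) -> tuple[MultilevelNetwork, AttributeTable]:
    """Generate one school; deterministic for a given seed.

    Pipeline: attributes → friendship growth (reciprocity, transitivity,
    gender match, attribute-distance decay, nomination cap) → PS selection by
    in-degree quantile with partial uptake → PS-created groups joined
    preferentially by the PS's friends → non-response deleting outgoing arcs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_students
    ids = [f"s{k:03d}" for k in range(n)]

    # 1. attributes
    gender = (rng.random(n) < config.male_proportion).astype(float)
    rho = config.attr_correlation
    corr = np.full((3, 3), rho) + np.eye(3) * (1 - rho)
    sds = np.asarray(config.attr_sds)
    cov = corr * np.outer(sds, sds)
    scores = rng.multivariate_normal(np.asarray(config.attr_means), cov, size=n)
    scores = np.clip(scores, 0.0, None)
    knowledge, norms, talking = scores.T
    dist = (np.abs(knowledge[:, None] - knowledge[None, :])
            + np.abs(norms[:, None] - norms[None, :])
            + np.abs(talking[:, None] - talking[None, :])) / 3.0

    # 2. friendship growth: one nomination per round in random order, so
    # reciprocity/transitivity act on partially built networks
    quota = np.minimum(config.nomination_cap,
                       rng.poisson(config.mean_nominations, size=n)).astype(int)
    quota = np.maximum(quota, 1)
    y = np.zeros((n, n), dtype=np.int8)
    base_w = np.exp(config.gender_match * (gender[:, None] == gender[None, :])
                    - config.distance_decay * dist)
    np.fill_diagonal(base_w, 0.0)
    for _ in range(int(quota.max())):
        order = rng.permutation(n)
        for i in order:
            if y[i].sum() >= quota[i]:
                continue
            common = np.minimum((y[i].astype(np.int32) @ y), 3)
            w = base_w[i] * np.exp(config.reciprocity_bonus * y[:, i]
                                   + config.transitivity_bonus * common)
            w[y[i] == 1] = 0.0
            w[i] = 0.0
            total = w.sum()
            if total <= 0:
                continue
            j = rng.choice(n, p=w / total)
            y[i, j] = 1

    # 3. peer supporters: nomination score ~ in-degree + noise, top quantile,
    # then partial uptake
    score = y.sum(axis=0) + rng.normal(0.0, 1.0, size=n)
    n_invited = max(1, int(round(config.ps_top_fraction * n)))
    invited = np.argsort(score)[::-1][:n_invited]
    ps = np.zeros(n, dtype=float)
    ps[invited[rng.random(n_invited) < config.ps_uptake]] = 1.0

    # 4. PS-created groups, membership aligned with friendship to the PS
    groups: list[str] = []
    members: list[np.ndarray] = []
    join_friend = min(1.0, config.baseline_join * config.affiliation_alignment)
    for p_idx in np.nonzero(ps)[0]:
        linked = (y[p_idx] == 1) | (y[:, p_idx] == 1)
        for g in range(config.groups_per_ps):
            prob = np.where(linked, join_friend, config.baseline_join)
            prob[p_idx] = 1.0  # the PS belongs to their own group
            members.append(rng.random(n) < prob)
            groups.append(f"g_{ids[p_idx]}_{g}")

    # 5. non-response: outgoing arcs of non-respondents are structurally absent
    respondent = rng.random(n) < config.response_rate
    y[~respondent, :] = 0

    z = (np.column_stack(members).astype(np.int8) if members
         else np.zeros((n, 0), dtype=np.int8))
    attrs = pd.DataFrame({
        "student": ids,
        "respondent": respondent.astype(int),
        "gender": gender,
        "ps": ps,
        "knowledge": np.where(respondent, np.round(knowledge, 3), np.nan),
        "norms": np.where(respondent, np.round(norms, 3), np.nan),
        "talking": np.where(respondent, np.round(talking, 3), np.nan),
    })
    arc_records = [(ids[i], ids[j]) for i, j in zip(*np.nonzero(y))]
    aff_records = [(ids[i], groups[g]) for i, g in zip(*np.nonzero(z))]
    return load_multilevel_network(arc_records, aff_records, attrs,
                                   max_out=config.nomination_cap, strict=True)


def generate_from_model(skeleton: MultilevelNetwork, theta, spec,
                        sampler_config: SamplerConfig,
                        attrs: AttributeTable | None = None) -> MultilevelNetwork:
    """One draw from the friendship model at ``theta`` on a fixed skeleton.

    The skeleton provides rosters, affiliations, respondent flags and the
    nomination cap; only the friendship arcs are resampled.  This is the
    input path for parameter-recovery experiments.
    """
    cfg = SamplerConfig(
        seed=sampler_config.seed,
        burn_in=sampler_config.burn_in,
        thinning=sampler_config.thinning if sampler_config.thinning else 1,
        n_samples=1,
        respect_max_out=sampler_config.respect_max_out,
        start=sampler_config.start,
        keep_networks=True,
    )
    batch = simulate(skeleton, theta, spec, cfg, attrs)
    out = skeleton.copy()
    out.y = batch.networks[-1].copy()
    conditioned = (cfg.respect_max_out if cfg.respect_max_out is not None
                   else getattr(spec, "condition_max_out", True))
    if not conditioned:
        out.max_out = out.n - 1  # the model places no cap on nominations
    out.validate(strict=True)
    return out


def write_school_files(net: MultilevelNetwork, attrs: AttributeTable,
                       directory, config: SchoolSimConfig | None = None) -> dict:
    """Emit the three delimited files plus a provenance record."""
    from pathlib import Path
    from .netdata import write_school

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "arcs": directory / "arcs.csv",
        "affiliations": directory / "affiliations.csv",
        "attributes": directory / "attributes.csv",
    }
    write_school(net, attrs, paths["arcs"], paths["affiliations"], paths["attributes"])
    if config is not None:
        prov = directory / "provenance.json"
        prov.write_text(json.dumps({"generator": "mergm.synthdata.generate_school",
                                    "config": asdict(config)}, indent=2, default=list))
        paths["provenance"] = prov
    return {k: str(v) for k, v in paths.items()}
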