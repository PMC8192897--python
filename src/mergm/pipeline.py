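"""Per-school fits and the multi-school report.

Each school is fitted independently (estimates are not comparable across
networks of different sizes, so no pooling layer exists); failures in one
school are reported in its section without aborting the others.  Effects are
tagged to the process-evaluation component they speak to:

* cross-level effects → implementation fidelity and delivery,
* peer-supporter actor effects → mechanisms of impact,
* remaining actor-relation (homophily/attribute) effects → context,
* structural effects → structural controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .effects import EffectTerm, ModelSpec, default_model_spec
from .estimator import EstimationConfig, EstimationError, FitResult, fit_mergm
from .gof import GOFReport, goodness_of_fit
from .netdata import AttributeTable, MultilevelNetwork, read_school, summarize
from .synthdata import SchoolSimConfig, generate_school

logger = logging.getLogger(__name__)

COMPONENT_TAGS = {
    "structural": "structural controls",
    "cross-level": "implementation fidelity",
}


def component_tag(term: EffectTerm) -> str:
    """Map one effect to the process-evaluation component it informs."""
    if term.family in COMPONENT_TAGS:
        return COMPONENT_TAGS[term.family]
    if term.attribute == "ps" or term.name.startswith("PSTalking"):
        return "mechanisms of impact"
    return "context"


@dataclass
class SchoolResult:
    name: str
    summary: dict
    fit: FitResult | None = None
    gof: GOFReport | None = None
    error: str | None = None


@dataclass
class StudyReport:
    spec: ModelSpec
    schools: list[SchoolResult]
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tags:
            self.tags = {t.label: component_tag(t) for t in self.spec.terms}


@dataclass
class StudyConfig:
    """One study: a shared model plus per-school inputs (files or generators)."""

    schools: list[dict]           # each: {name, files: {...}} or {name, generate: {...}}
    spec: ModelSpec
    estimation: dict = field(default_factory=dict)
    gof_samples: int = 500
    run_gof: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        raw = yaml.safe_load(text)
        if not raw.get("schools"):
            raise ValueError("study config lists no schools")
        spec = (ModelSpec.from_yaml(yaml.safe_dump(raw["model"]))
                if "model" in raw else default_model_spec())
        return cls(schools=raw["schools"], spec=spec,
                   estimation=raw.get("estimation", {}),
                   gof_samples=int(raw.get("gof_samples", 500)),
                   run_gof=bool(raw.get("run_gof", True)),
                   seed=int(raw.get("seed", 0)))


def _load_school(entry: dict, seed: int) -> tuple[str, MultilevelNetwork, AttributeTable]:
    name = entry.get("name", "school")
    if "files" in entry:
        f = entry["files"]
        net, attrs = read_school(f["arcs"], f["affiliations"], f["attributes"],
                                 max_out=int(entry.get("max_out", 6)))
    elif "generate" in entry:
        params = dict(entry["generate"])
        params.setdefault("seed", seed)
        net, attrs = generate_school(SchoolSimConfig(**params))
    else:
        raise ValueError(f"school entry {name!r} has neither 'files' nor 'generate'")
    return name, net, attrs


def run_study(config: StudyConfig) -> StudyReport:
    """Fit every configured school; isolate per-school failures."""
    if not config.schools:
        raise ValueError("no schools configured")
    results: list[SchoolResult] = []
    for k, entry in enumerate(config.schools):
        school_seed = int(config.seed) + 1000 * (k + 1)
        try:
            name, net, attrs = _load_school(entry, school_seed)
        except Exception as exc:  # malformed entry: report and continue
            results.append(SchoolResult(name=entry.get("name", f"school{k+1}"),
                                        summary={}, error=str(exc)))
            continue
        res = SchoolResult(name=name, summary=summarize(net, attrs))
        try:
            est = EstimationConfig(seed=school_seed, **config.estimation)
            res.fit = fit_mergm(net, attrs, config.spec, est)
            if config.run_gof:
                res.gof = goodness_of_fit(
                    net, attrs, res.fit, config.spec,
                    n_samples=config.gof_samples, seed=school_seed + 17,
                    allow_nonconverged=True)
        except EstimationError as exc:
            res.error = f"{type(exc).__name__}: {exc}"
            logger.warning("school %s failed: %s", name, res.error)
        results.append(res)
    return StudyReport(spec=config.spec, schools=results)


def render_table(report: StudyReport) -> str:
    """Text table mirroring the published layout: schools as column pairs
    (Parameter, Stderr), effects as rows grouped by family, an asterisk on
    significant rows, three decimals."""
    groups = [("Structural effects", "structural"),
              ("Actor-relation interaction effects", "actor-relation"),
              ("Cross-level effects", "cross-level")]
    name_w = max([len(t.label) for t in report.spec.terms] + [28])
    fitted = [s for s in report.schools]
    header = " " * name_w
    for s in fitted:
        header += f"  {s.name:>18}"
    sub = " " * name_w + ("  " + f"{'Parameter':>11}{'Stderr':>7}") * len(fitted)
    lines = [header, sub]
    for title, family in groups:
        rows = [(k, t) for k, t in enumerate(report.spec.terms) if t.family == family]
        if not rows:
            continue
        lines.append(title)
        for k, term in rows:
            line = f"{term.label:<{name_w}}"
            for s in fitted:
                if s.fit is None:
                    line += f"  {'—':>11}{'':>7}"
                    continue
                th, se = s.fit.theta[k], s.fit.se[k]
                star = "*" if s.fit.significant[k] else ""
                line += f"  {th:>10.3f}{star:<1}{se:>6.3f}"
            lines.append(line)
    for s in fitted:
        if s.error:
            lines.append(f"note: {s.name} not fitted — {s.error}")
        elif s.fit is not None and not s.fit.converged:
            lines.append(f"note: {s.name} did not reach the convergence criterion")
    return "\n".join(lines) + "\n"
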