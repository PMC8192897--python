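"""Effect terms: graph statistics and change statistics of the friendship model.

The model is an exponential family over the directed friendship arcs ``y``
with fixed group affiliations ``z``:  P(y) ∝ exp(θ·s(y)), where each
component of ``s`` counts (or geometrically damps) one local configuration.

Three families of terms are supported:

* **structural** — density (ArcA), reciprocity, alternating in/out-stars
  (popularity/activity spread, AinSA/AoutSA), alternating path closure
  (ATA-T) and alternating multiple two-paths (A2PA-T).  The alternating
  statistics damp higher-order stars/two-paths with a smoothing constant
  λ ≥ 1 to keep estimation away from degenerate regions.
* **actor-relation** — Sender, Receiver, Interaction (binary homophily) and
  Difference (continuous heterophily) for a named covariate, plus the
  peer-supporter × talking products on the sender/receiver side.
* **cross-level** — in/out-degree × group-membership two-stars (In2StarAX,
  Out2StarAX), arcs whose endpoints share a group (TXAXarc) and arcs whose
  endpoints sit in distinct groups (L3XAX).  Affiliations never change, so
  all four are dyad-independent given ``z``.

Closed forms, with r = 1 − 1/λ, d_in/d_out the degrees, TP(i,j) the directed
two-path count, dX(i) = Σ_g z_ig and s(i,j) = Σ_g z_ig·z_jg:

====================  ====================================================
ArcA                  Σ y_ij
ReciprocityA          Σ_{i<j} y_ij·y_ji
AinSA                 λ² Σ_i [r^{d_in(i)} + d_in(i)/λ − 1]
AoutSA                λ² Σ_i [r^{d_out(i)} + d_out(i)/λ − 1]
ATA-T                 λ Σ_{y_ij=1} [1 − r^{TP(i,j)}]
A2PA-T                λ Σ_{i≠j} [1 − r^{TP(i,j)}]
Sender(x)             Σ_{y_ij=1} x_i          (Receiver: x_j)
Interaction(b)        Σ_{y_ij=1} b_i·b_j
Difference(x)         Σ_{y_ij=1} |x_i − x_j|
PSTalkingSender       Σ_{y_ij=1} ps_i·talk_i  (Receiver: ps_j·talk_j)
In2StarAX             Σ_i d_in(i)·dX(i)       (Out2StarAX: d_out)
TXAXarc               Σ_{y_ij=1} s(i,j)
L3XAX                 Σ_{y_ij=1} [dX(i)·dX(j) − s(i,j)]
====================  ====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import _mcmc
from .netdata import (
    AttributeTable,
    BINARY_ATTRIBUTES,
    CONTINUOUS_ATTRIBUTES,
    MultilevelNetwork,
    NetworkDataError,
    free_tie_variables,
)

logger = logging.getLogger(__name__)

STRUCTURAL_TERMS = ("ArcA", "ReciprocityA", "AinSA", "AoutSA", "ATA-T", "A2PA-T")
ACTOR_TERMS = ("Sender", "Receiver", "Interaction", "Difference",
               "PSTalkingSender", "PSTalkingReceiver")
CROSS_LEVEL_TERMS = ("In2StarAX", "Out2StarAX", "TXAXarc", "L3XAX")
ALTERNATING_TERMS = ("AinSA", "AoutSA", "ATA-T", "A2PA-T")
_NEED_ATTRIBUTE = ("Sender", "Receiver", "Interaction", "Difference")

_ATTR_LABEL = {"gender": "Gender", "ps": "PS", "knowledge": "Knowledge",
               "norms": "Norms", "talking": "Talking"}


@dataclass(frozen=True)
class EffectTerm:
    """One model term: a family name, an optional covariate, a smoothing λ."""

    name: str
    attribute: str | None = None
    lam: float = 2.0

    def __post_init__(self):
        known = STRUCTURAL_TERMS + ACTOR_TERMS + CROSS_LEVEL_TERMS
        if self.name not in known:
            raise NetworkDataError(f"unknown effect term {self.name!r}")
        if self.name in _NEED_ATTRIBUTE and not self.attribute:
            raise NetworkDataError(f"term {self.name!r} requires an attribute")
        if self.name not in _NEED_ATTRIBUTE and self.attribute:
            raise NetworkDataError(f"term {self.name!r} does not take an attribute")
        if self.name == "Interaction" and self.attribute not in BINARY_ATTRIBUTES:
            raise NetworkDataError("Interaction is defined for binary attributes only")
        if self.name == "Difference" and self.attribute not in CONTINUOUS_ATTRIBUTES:
            raise NetworkDataError("Difference is defined for continuous attributes only")
        if self.lam < 1:
            raise NetworkDataError("smoothing constant lambda must be >= 1")

    @property
    def label(self) -> str:
        """Reporting label, e.g. ``Gender-Sender`` or ``PS Talking-Sender``."""
        if self.name == "PSTalkingSender":
            return "PS Talking-Sender"
        if self.name == "PSTalkingReceiver":
            return "PS Talking-Receiver"
        if self.attribute:
            return f"{_ATTR_LABEL.get(self.attribute, self.attribute.capitalize())}-{self.name}"
        return self.name

    @property
    def family(self) -> str:
        if self.name in STRUCTURAL_TERMS:
            return "structural"
        if self.name in CROSS_LEVEL_TERMS:
            return "cross-level"
        return "actor-relation"


@dataclass
class ModelSpec:
    """Ordered effect list plus the sample-space constraints of the model."""

    terms: list[EffectTerm]
    condition_max_out: bool = True

    def __post_init__(self):
        keys = [(t.name, t.attribute) for t in self.terms]
        if len(set(keys)) != len(keys):
            raise NetworkDataError("duplicate (name, attribute) effect terms")
        if not any(t.name == "ArcA" for t in self.terms):
            raise NetworkDataError("a model needs a density-type term (ArcA)")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def index_of(self, name: str, attribute: str | None = None) -> int:
        for k, t in enumerate(self.terms):
            if t.name == name and t.attribute == attribute:
                return k
        raise KeyError((name, attribute))

    # -- serialisation -----------------------------------------------------
    def to_yaml(self) -> str:
        payload = {
            "condition_max_out": self.condition_max_out,
            "terms": [
                {k: v for k, v in
                 (("name", t.name), ("attribute", t.attribute), ("lambda", t.lam))
                 if v is not None}
                for t in self.terms
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        payload = yaml.safe_load(text)
        terms = [
            EffectTerm(d["name"], d.get("attribute"), float(d.get("lambda", 2.0)))
            for d in payload["terms"]
        ]
        return cls(terms, condition_max_out=bool(payload.get("condition_max_out", True)))


def default_model_spec(lam: float = 2.0) -> ModelSpec:
    """The full 26-term per-school specification used in reporting."""
    terms = [
        EffectTerm("ArcA"),
        EffectTerm("ReciprocityA"),
        EffectTerm("AinSA", lam=lam),
        EffectTerm("AoutSA", lam=lam),
        EffectTerm("ATA-T", lam=lam),
        EffectTerm("A2PA-T", lam=lam),
        EffectTerm("Sender", "gender"),
        EffectTerm("Receiver", "gender"),
        EffectTerm("Interaction", "gender"),
        EffectTerm("Sender", "ps"),
        EffectTerm("Receiver", "ps"),
        EffectTerm("Sender", "knowledge"),
        EffectTerm("Receiver", "knowledge"),
        EffectTerm("Difference", "knowledge"),
        EffectTerm("Sender", "norms"),
        EffectTerm("Receiver", "norms"),
        EffectTerm("Difference", "norms"),
        EffectTerm("Sender", "talking"),
        EffectTerm("Receiver", "talking"),
        EffectTerm("Difference", "talking"),
        EffectTerm("PSTalkingSender"),
        EffectTerm("PSTalkingReceiver"),
        EffectTerm("In2StarAX"),
        EffectTerm("Out2StarAX"),
        EffectTerm("TXAXarc"),
        EffectTerm("L3XAX"),
    ]
    return ModelSpec(terms)


# ---------------------------------------------------------------------------
# design: compiled-friendly encoding of a (network, attributes, spec) triple


def resolve_attribute(attrs: AttributeTable, name: str, *, respondent: np.ndarray,
                      center: bool = False) -> np.ndarray:
    """Attribute vector with missingness resolved for use in statistics.

    Continuous scores: missing values (non-respondents, item non-response)
    are imputed with the respondent mean, centring the influence of missing
    actors; binary flags: missing -> 0.  Both choices are logged.
    """
    x = attrs.values(name).astype(float)
    miss = ~np.isfinite(x)
    if name in BINARY_ATTRIBUTES:
        if miss.any():
            logger.info("attribute %s: %d missing value(s) set to 0", name, miss.sum())
            x = np.where(miss, 0.0, x)
    else:
        obs = np.isfinite(x) & respondent
        fill = float(x[obs].mean()) if obs.any() else 0.0
        if miss.any():
            logger.info("attribute %s: %d missing value(s) imputed with respondent mean %.3f",
                        name, miss.sum(), fill)
            x = np.where(miss, fill, x)
        if center:
            x = x - fill
    return x


class Design:
    """Compiled encoding of one model on one network (fixed covariates)."""

    def __init__(self, net: MultilevelNetwork, attrs: AttributeTable | None,
                 spec: ModelSpec, *, center: bool = False):
        net.validate(strict=True)
        self.net = net
        self.spec = spec
        n = net.n
        k = len(spec.terms)
        self.codes = np.zeros(k, dtype=np.int64)
        self.lams = np.full(k, 2.0)
        self.D = np.zeros((k, n, n))
        dX = net.group_degrees().astype(float)
        shared = (net.z.astype(np.int64) @ net.z.astype(np.int64).T).astype(float)

        def attr_vec(name):
            if attrs is None:
                raise NetworkDataError(f"attribute table required for attribute {name!r}")
            return resolve_attribute(attrs, name, respondent=net.respondent, center=center)

        code_map = {"ReciprocityA": _mcmc.CODE_RECIP, "AinSA": _mcmc.CODE_AINS,
                    "AoutSA": _mcmc.CODE_AOUTS, "ATA-T": _mcmc.CODE_ATA,
                    "A2PA-T": _mcmc.CODE_A2PA}
        ones = np.ones(n)
        for t, term in enumerate(spec.terms):
            self.lams[t] = term.lam
            if term.name in code_map:
                self.codes[t] = code_map[term.name]
                continue
            self.codes[t] = _mcmc.CODE_DYADIC
            if term.name == "ArcA":
                M = np.outer(ones, ones)
            elif term.name == "Sender":
                M = np.outer(attr_vec(term.attribute), ones)
            elif term.name == "Receiver":
                M = np.outer(ones, attr_vec(term.attribute))
            elif term.name == "Interaction":
                b = attr_vec(term.attribute)
                M = np.outer(b, b)
            elif term.name == "Difference":
                x = attr_vec(term.attribute)
                M = np.abs(x[:, None] - x[None, :])
            elif term.name == "PSTalkingSender":
                M = np.outer(attr_vec("ps") * attr_vec("talking"), ones)
            elif term.name == "PSTalkingReceiver":
                M = np.outer(ones, attr_vec("ps") * attr_vec("talking"))
            elif term.name == "In2StarAX":
                M = np.outer(ones, dX)
            elif term.name == "Out2StarAX":
                M = np.outer(dX, ones)
            elif term.name == "TXAXarc":
                M = shared.copy()
            elif term.name == "L3XAX":
                M = np.outer(dX, dX) - shared
            else:  # pragma: no cover - exhaustive above
                raise NetworkDataError(f"unhandled term {term.name!r}")
            np.fill_diagonal(M, 0.0)
            self.D[t] = M

        self.senders = np.nonzero(net.respondent)[0].astype(np.int64)
        self.free_count = len(self.senders) * (n - 1)
        self.max_out = net.max_out
        self.labels = spec.labels

    # -- state -------------------------------------------------------------
    def make_state(self, y: np.ndarray | None = None):
        """Build the (y, TP, din, dout) arrays the kernel mutates in place."""
        n = self.net.n
        if y is None:
            y = np.zeros((n, n), dtype=np.int8)
        else:
            y = np.ascontiguousarray(np.asarray(y, dtype=np.int8)).copy()
        yi = y.astype(np.int32)
        TP = np.ascontiguousarray(yi @ yi)
        return y, TP, yi.sum(axis=0).astype(np.int32), yi.sum(axis=1).astype(np.int32)

    def statistics_from_state(self, y, TP) -> np.ndarray:
        """Full recount of every term from an explicit state (vectorised)."""
        out = np.empty(len(self.codes))
        yf = y.astype(float)
        din = yf.sum(axis=0)
        dout = yf.sum(axis=1)
        for t, c in enumerate(self.codes):
            lam = self.lams[t]
            r = 1.0 - 1.0 / lam
            if c == _mcmc.CODE_DYADIC:
                out[t] = float((yf * self.D[t]).sum())
            elif c == _mcmc.CODE_RECIP:
                out[t] = float((yf * yf.T).sum()) / 2.0
            elif c == _mcmc.CODE_AINS:
                out[t] = lam * lam * float((r ** din + din / lam - 1.0).sum())
            elif c == _mcmc.CODE_AOUTS:
                out[t] = lam * lam * float((r ** dout + dout / lam - 1.0).sum())
            elif c == _mcmc.CODE_ATA:
                out[t] = lam * float((yf * (1.0 - r ** TP)).sum())
            else:
                M = 1.0 - r ** TP.astype(float)
                out[t] = lam * float(M.sum() - np.trace(M))
        return out

    def statistics(self, y: np.ndarray | None = None) -> np.ndarray:
        y0 = self.net.y if y is None else np.asarray(y, dtype=np.int8)
        yi = y0.astype(np.int32)
        return self.statistics_from_state(y0, yi @ yi)

    def change_statistics(self, dyad: tuple[int, int], y: np.ndarray | None = None) -> np.ndarray:
        """z(y with arc on) − z(y with arc off) for one free dyad, incremental."""
        i, j = dyad
        if i == j or not (0 <= i < self.net.n) or not self.net.respondent[i]:
            raise NetworkDataError(
                f"dyad ({i}, {j}) is outside the free tie-variable set "
                "(sender must be a respondent, no self-arcs)")
        ys, TP, din, dout = self.make_state(self.net.y if y is None else y)
        if ys[i, j] == 1:
            _mcmc._apply_remove(ys, TP, din, dout, i, j)
        dz = np.empty(len(self.codes))
        _mcmc.delta_add(ys, TP, din, dout, self.D, self.codes, self.lams, i, j, dz)
        return dz


# ---------------------------------------------------------------------------
# public operations


def structural_statistics(net: MultilevelNetwork, terms: list[EffectTerm]) -> np.ndarray:
    """Counts of the purely structural configurations (no covariates needed)."""
    for t in terms:
        if t.name not in STRUCTURAL_TERMS:
            raise NetworkDataError(f"{t.name!r} is not a structural term")
    spec = ModelSpec([EffectTerm("ArcA")] + [t for t in terms if t.name != "ArcA"])
    stats = Design(net, None, spec).statistics()
    return np.array([stats[spec.index_of(t.name, t.attribute)] for t in terms])


def actor_relation_statistics(net: MultilevelNetwork, attrs: AttributeTable,
                              term: EffectTerm) -> float:
    if term.name not in ACTOR_TERMS:
        raise NetworkDataError(f"{term.name!r} is not an actor-relation term")
    spec = ModelSpec([EffectTerm("ArcA"), term])
    return float(Design(net, attrs, spec).statistics()[1])


def cross_level_statistics(net: MultilevelNetwork, terms: list[EffectTerm]) -> np.ndarray:
    for t in terms:
        if t.name not in CROSS_LEVEL_TERMS:
            raise NetworkDataError(f"{t.name!r} is not a cross-level term")
    spec = ModelSpec([EffectTerm("ArcA")] + list(terms))
    return Design(net, None, spec).statistics()[1:]


def statistics(net: MultilevelNetwork, attrs: AttributeTable | None,
               spec: ModelSpec) -> np.ndarray:
    """Observed statistic vector z(y) for every term of ``spec``, in order."""
    return Design(net, attrs, spec).statistics()


def change_statistics(net: MultilevelNetwork, attrs: AttributeTable | None,
                      spec: ModelSpec, dyad: tuple[int, int]) -> np.ndarray:
    """Toggle difference for one dyad; equals the full-recount difference."""
    return Design(net, attrs, spec).change_statistics(dyad)


def load_default_model_yaml() -> ModelSpec:
    """The shipped 26-row model configuration."""
    text = resources.files("mergm.data").joinpath("default_model.yaml").read_text()
    return ModelSpec.from_yaml(text)
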