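"""Multilevel network data model.

A school network has two node sets: students (level A), joined by a binary
*directed* friendship adjacency ``y``, and online groups (level B), joined to
students by a binary *undirected* affiliation incidence ``z``.  Friendship
ties are the modelled variables; affiliations are fixed exogenous covariates.

Two survey constraints shape the space of modelled tie variables:

* only survey respondents report friendships, so every arc whose sender is a
  non-respondent is a *structural zero* — fixed absent, never modelled;
* respondents could nominate at most ``max_out`` friends (six in the study
  design), so the model space is conditioned on that out-degree cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = ("gender", "ps", "knowledge", "norms", "talking")
BINARY_ATTRIBUTES = ("gender", "ps")
CONTINUOUS_ATTRIBUTES = ("knowledge", "norms", "talking")


class NetworkDataError(ValueError):
    """Raised when records violate the multilevel-network data model."""


@dataclass
class MultilevelNetwork:
    """Directed student friendship arcs plus fixed student-group affiliations.

    Parameters
    ----------
    students, groups
        Ordered rosters of unique opaque string identifiers.
    y
        ``(n, n)`` binary arc matrix, ``y[i, j] = 1`` iff student ``i``
        nominated student ``j``.  The diagonal is structurally zero.
    z
        ``(n, m)`` binary affiliation incidence over groups.
    respondent
        Boolean flag per student; arcs may only leave respondents.
    max_out
        Nomination cap applied to respondent out-degrees.
    """

    students: list[str]
    groups: list[str]
    y: np.ndarray
    z: np.ndarray
    respondent: np.ndarray
    max_out: int = 6

    def __post_init__(self) -> None:
        self.students = [str(s) for s in self.students]
        self.groups = [str(g) for g in self.groups]
        self.y = np.ascontiguousarray(np.asarray(self.y, dtype=np.int8))
        self.z = np.ascontiguousarray(np.asarray(self.z, dtype=np.int8))
        self.respondent = np.asarray(self.respondent, dtype=bool)
        self._index = {s: k for k, s in enumerate(self.students)}

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.students)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index_of(self, student: str) -> int:
        return self._index[str(student)]

    def in_degrees(self) -> np.ndarray:
        return self.y.sum(axis=0)

    def out_degrees(self) -> np.ndarray:
        return self.y.sum(axis=1)

    def group_degrees(self) -> np.ndarray:
        """Number of group memberships per student (``dX``)."""
        return self.z.sum(axis=1)

    def arcs(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.y)
        return [(self.students[i], self.students[j]) for i, j in zip(ii, jj)]

    def affiliation_pairs(self) -> list[tuple[str, str]]:
        ii, gg = np.nonzero(self.z)
        return [(self.students[i], self.groups[g]) for i, g in zip(ii, gg)]

    def copy(self) -> "MultilevelNetwork":
        return MultilevelNetwork(
            list(self.students), list(self.groups), self.y.copy(),
            self.z.copy(), self.respondent.copy(), self.max_out,
        )

    # -- validation --------------------------------------------------------
    def validate(self, strict: bool = True) -> None:
        """Check the structural invariants of the data model.

        Raises :class:`NetworkDataError` on violation.  With
        ``strict=False`` only shape-level impossibilities raise.
        """
        n, m = self.n, self.n_groups
        if self.y.shape != (n, n):
            raise NetworkDataError(f"arc matrix shape {self.y.shape} != ({n}, {n})")
        if self.z.shape != (n, m):
            raise NetworkDataError(f"affiliation shape {self.z.shape} != ({n}, {m})")
        if len(set(self.students)) != n:
            raise NetworkDataError("duplicate student identifiers in roster")
        if len(set(self.groups)) != m:
            raise NetworkDataError("duplicate group identifiers in roster")
        if n and np.any(np.diag(self.y) != 0):
            raise NetworkDataError("self-arcs are not allowed")
        if not np.isin(self.y, (0, 1)).all() or not np.isin(self.z, (0, 1)).all():
            raise NetworkDataError("adjacency entries must be binary")
        if strict:
            bad = np.nonzero(~self.respondent & (self.out_degrees() > 0))[0]
            if bad.size:
                raise NetworkDataError(
                    "structural-zero rule violated: arcs sent by non-respondent(s) "
                    + ", ".join(self.students[i] for i in bad[:5])
                    + " (a tie from a non-respondent is considered impossible)"
                )
            over = np.nonzero(self.respondent & (self.out_degrees() > self.max_out))[0]
            if over.size:
                raise NetworkDataError(
                    f"respondent out-degree exceeds the nomination cap of {self.max_out}: "
                    + ", ".join(self.students[i] for i in over[:5])
                )


@dataclass
class AttributeTable:
    """Per-student covariates aligned with a network roster.

    Held as a :class:`pandas.DataFrame` indexed by student identifier with
    columns ``respondent, gender, ps, knowledge, norms, talking``.  Gender is
    coded 1 = male, 0 = female; ``ps`` flags trained peer supporters.  NaN
    marks item non-response; non-respondents typically miss the three
    questionnaire scores (knowledge, norms, talking) but keep roster-derived
    gender and the peer-supporter role flag.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        for col in ATTRIBUTE_COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = np.nan
            self.frame[col] = pd.to_numeric(self.frame[col], errors="coerce")
        for col in BINARY_ATTRIBUTES:
            vals = self.frame[col].dropna()
            if not vals.isin((0, 1)).all():
                raise NetworkDataError(f"binary attribute {col!r} has values outside {{0,1}}")
        cont = self.frame[list(CONTINUOUS_ATTRIBUTES)]
        if np.isinf(cont.to_numpy(dtype=float)).any():
            raise NetworkDataError("continuous attributes must be finite when present")

    def values(self, name: str) -> np.ndarray:
        """Raw (possibly NaN) attribute vector in roster order."""
        if name not in self.frame.columns:
            raise NetworkDataError(f"unknown attribute {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def align(self, students: Sequence[str]) -> "AttributeTable":
        missing = set(map(str, students)) - set(self.frame.index)
        if missing:
            raise NetworkDataError(f"attribute rows missing for students: {sorted(missing)[:5]}")
        return AttributeTable(self.frame.loc[list(map(str, students))])


@dataclass(frozen=True)
class TieVariableSet:
    """The free (modelled) ordered pairs: sender a respondent, sender != receiver."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in set(self.pairs)


def free_tie_variables(net: MultilevelNetwork) -> TieVariableSet:
    """Enumerate modelled tie variables in deterministic sender-major roster order.

    For a full-response network of ``n`` students this is all ``n(n-1)``
    ordered pairs; each non-respondent removes its ``n-1`` outgoing pairs.
    """
    pairs = tuple(
        (i, j)
        for i in range(net.n)
        if net.respondent[i]
        for j in range(net.n)
        if j != i
    )
    return TieVariableSet(pairs)


def _dedupe(records: Iterable[tuple], what: str) -> list[tuple]:
    seen: dict = {}
    dupes = 0
    for rec in records:
        key = tuple(str(x) for x in rec)
        if key in seen:
            dupes += 1
        seen[key] = True
    if dupes:
        logger.warning("%d duplicate %s record(s) collapsed (binary tie model)", dupes, what)
    return list(seen)


def load_multilevel_network(
    arc_records: Iterable[tuple],
    affiliation_records: Iterable[tuple],
    attribute_records: pd.DataFrame | Iterable[dict],
    *,
    max_out: int = 6,
    strict: bool = True,
) -> tuple[MultilevelNetwork, AttributeTable]:
    """Build a validated :class:`MultilevelNetwork` + :class:`AttributeTable`.

    ``arc_records`` are ``(sender, receiver)`` pairs, ``affiliation_records``
    are ``(student, group)`` pairs, and ``attribute_records`` is a table with
    a ``student`` column (or index) plus ``respondent`` and the attribute
    columns.  The student roster is taken from the attribute table in file
    order; the group roster from first appearance in the affiliation records.

    Under ``strict=True`` (default) structural violations — an arc sent by a
    non-respondent, a self-arc, a respondent above the nomination cap — raise
    :class:`NetworkDataError`.  Under ``strict=False`` offending arc records
    are dropped with a warning, mirroring messy survey exports.
    """
    if not isinstance(attribute_records, pd.DataFrame):
        attribute_records = pd.DataFrame(list(attribute_records))
    attr = attribute_records.copy()
    if "student" in attr.columns:
        attr["student"] = attr["student"].astype(str)
        attr = attr.set_index("student")
    attr.index = attr.index.astype(str)
    if attr.index.has_duplicates:
        raise NetworkDataError("duplicate student rows in attribute table")

    students = list(attr.index)
    index = {s: k for k, s in enumerate(students)}
    if "respondent" not in attr.columns:
        attr["respondent"] = 1
    respondent = pd.to_numeric(attr["respondent"], errors="coerce").fillna(0).astype(bool).to_numpy()

    arc_records = _dedupe(arc_records, "arc")
    affiliation_records = _dedupe(affiliation_records, "affiliation")

    groups: list[str] = []
    gindex: dict[str, int] = {}
    for s, g in affiliation_records:
        if s not in index:
            raise NetworkDataError(f"unknown student identifier in affiliation record: {s!r}")
        if g not in gindex:
            gindex[g] = len(groups)
            groups.append(g)

    n, m = len(students), len(groups)
    y = np.zeros((n, n), dtype=np.int8)
    z = np.zeros((n, m), dtype=np.int8)
    for s, g in affiliation_records:
        z[index[s], gindex[g]] = 1

    for s, r in arc_records:
        if s not in index or r not in index:
            raise NetworkDataError(f"unknown student identifier in arc record: ({s!r}, {r!r})")
        i, j = index[s], index[r]
        if i == j:
            raise NetworkDataError(f"self-arc on student {s!r}")
        if not respondent[i]:
            msg = (
                f"arc ({s!r}, {r!r}) violates the structural-zero rule: its sender is a "
                "non-respondent, and a tie from a non-respondent to a participant is "
                "considered impossible"
            )
            if strict:
                raise NetworkDataError(msg)
            logger.warning("%s — record dropped", msg)
            continue
        y[i, j] = 1

    net = MultilevelNetwork(students, groups, y, z, respondent, max_out=max_out)
    if strict:
        net.validate(strict=True)
    else:
        # demote cap violations: drop latest arcs beyond the cap, roster order
        for i in np.nonzero(net.respondent & (net.out_degrees() > max_out))[0]:
            recv = np.nonzero(net.y[i])[0]
            drop = recv[max_out:]
            logger.warning(
                "respondent %s exceeds the nomination cap (%d > %d); dropping %d arc(s)",
                students[i], len(recv), max_out, len(drop),
            )
            net.y[i, drop] = 0
        net.validate(strict=True)
    table = AttributeTable(attr.drop(columns=["respondent"], errors="ignore")).align(students)
    table.frame.insert(0, "respondent", respondent.astype(int))
    return net, table


# -- file I/O ---------------------------------------------------------------

def read_school(
    arcs_path, affiliations_path, attributes_path, *, max_out: int = 6, strict: bool = True
) -> tuple[MultilevelNetwork, AttributeTable]:
    """Read the three delimited files of one school.

    ``arcs``: header ``sender,receiver``; ``affiliations``: ``student,group``;
    ``attributes``: ``student,respondent,gender,ps,knowledge,norms,talking``
    with empty cells meaning missing.
    """
    arcs = pd.read_csv(arcs_path, dtype=str)
    affs = pd.read_csv(affiliations_path, dtype=str)
    attrs = pd.read_csv(attributes_path, dtype={"student": str})
    return load_multilevel_network(
        arcs[["sender", "receiver"]].itertuples(index=False, name=None),
        affs[["student", "group"]].itertuples(index=False, name=None),
        attrs,
        max_out=max_out,
        strict=strict,
    )


def write_school(net: MultilevelNetwork, attrs: AttributeTable,
                 arcs_path, affiliations_path, attributes_path) -> None:
    """Write the canonical three-file representation (round-trips with read_school)."""
    pd.DataFrame(net.arcs(), columns=["sender", "receiver"]).to_csv(arcs_path, index=False)
    pd.DataFrame(net.affiliation_pairs(), columns=["student", "group"]).to_csv(
        affiliations_path, index=False)
    out = attrs.frame.copy()
    out.index.name = "student"
    out.to_csv(attributes_path)


def write_matrices(net: MultilevelNetwork, adjacency_path, incidence_path) -> None:
    """Whitespace-delimited square adjacency and student-by-group incidence (roster order)."""
    np.savetxt(adjacency_path, net.y, fmt="%d")
    np.savetxt(incidence_path, net.z, fmt="%d")


def summarize(net: MultilevelNetwork, attrs: AttributeTable | None = None) -> dict:
    """Descriptive counts: sizes, density over the free tie variables, response rate."""
    free = len(free_tie_variables(net))
    n_arcs = int(net.y.sum())
    out = {
        "students": net.n,
        "respondents": int(net.respondent.sum()),
        "arcs": n_arcs,
        "groups": net.n_groups,
        "affiliations": int(net.z.sum()),
        "free_tie_variables": free,
        "density": (n_arcs / free) if free else 0.0,
        "response_proportion": float(net.respondent.mean()) if net.n else 0.0,
    }
    if attrs is not None:
        for col in ATTRIBUTE_COLUMNS:
            vals = attrs.values(col)
            out[f"mean_{col}"] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return out
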