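"""Data model and line-oriented dialect for rule-based network models.

A model file declares nodes with initial activities, then reactions.  Each
reaction has a rate coefficient and participant lines; a participant names
its role (``pro``/``sub``/``act``/``inh``), a node, and a six-integer rule
vector::

    node ATP 0.7
    node MRSP 0.8

    Reaction MRSP_ATP 0.8
    pro ATP 5 5 5 5 5 0
    act MRSP 0 1 2 3 4 5

Products (``pro``) and substrates (``sub``) are changed by the reaction;
activators (``act``) and inhibitors (``inh``) only modulate its rate.  All
four roles contribute a multiplicative rate factor through their rule
vector.  ``#`` starts a comment; blank lines are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .fuzzy_core import N_LEVELS, RuleVector

__all__ = [
    "ROLES",
    "ModelFormatError",
    "NodeDef",
    "Participant",
    "Reaction",
    "ModelSpec",
    "parse_model",
    "serialize_model",
    "count_structure",
    "signed_interaction_graph",
    "interaction_digraph",
]

ROLES = ("pro", "sub", "act", "inh")


class ModelFormatError(ValueError):
    """Raised on malformed model text; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class NodeDef:
    name: str
    initial_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_value <= 1.0:
            raise ValueError(
                f"node {self.name}: initial value {self.initial_value} outside [0, 1]"
            )


@dataclass(frozen=True)
class Participant:
    role: str
    node: str
    rule: RuleVector

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown participant role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    name: str
    rate_coefficient: float
    participants: Tuple[Participant, ...]

    def __post_init__(self) -> None:
        if self.rate_coefficient < 0:
            raise ValueError(f"reaction {self.name}: negative rate coefficient")
        if not self.participants:
            raise ValueError(f"reaction {self.name}: needs at least one participant")
        object.__setattr__(self, "participants", tuple(self.participants))


@dataclass(frozen=True)
class ModelSpec:
    nodes: Tuple[NodeDef, ...]
    reactions: Tuple[Reaction, ...]
    metadata: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "metadata", tuple(self.metadata))
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate node declaration(s): {', '.join(dup)}")
        rnames = [r.name for r in self.reactions]
        if len(set(rnames)) != len(rnames):
            dup = sorted({n for n in rnames if rnames.count(n) > 1})
            raise ValueError(f"duplicate reaction name(s): {', '.join(dup)}")
        known = set(names)
        for r in self.reactions:
            for p in r.participants:
                if p.node not in known:
                    raise ValueError(
                        f"reaction {r.name}: participant references "
                        f"undeclared node {p.node!r}"
                    )

    # -- convenience accessors -------------------------------------------
    @property
    def node_names(self) -> Tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def initial_state(self) -> Dict[str, float]:
        return {n.name: n.initial_value for n in self.nodes}

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(f"no reaction named {name!r}")

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def with_rate(self, reaction_name: str, rate: float) -> "ModelSpec":
        """Return a copy with one reaction's rate coefficient replaced."""
        self.reaction(reaction_name)  # raise early if absent
        new = tuple(
            replace(r, rate_coefficient=rate) if r.name == reaction_name else r
            for r in self.reactions
        )
        return replace(self, reactions=new)

    def with_rates(self, rates: Dict[str, float]) -> "ModelSpec":
        for name in rates:
            self.reaction(name)
        new = tuple(
            replace(r, rate_coefficient=rates[r.name]) if r.name in rates else r
            for r in self.reactions
        )
        return replace(self, reactions=new)


# -- parsing --------------------------------------------------------------

def _parse_rule(tokens: List[str], lineno: int) -> RuleVector:
    if len(tokens) != N_LEVELS:
        raise ModelFormatError(
            f"rule vector needs {N_LEVELS} integers, got {len(tokens)}", lineno
        )
    values = []
    for t in tokens:
        try:
            v = int(t)
        except ValueError:
            raise ModelFormatError(f"rule entry {t!r} is not an integer", lineno)
        if not 0 <= v < N_LEVELS:
            raise ModelFormatError(
                f"rule entry {v} outside 0..{N_LEVELS - 1}", lineno
            )
        values.append(v)
    return RuleVector(tuple(values))


def parse_model(text: str) -> ModelSpec:
    """Parse model text into a validated :class:`ModelSpec`.

    Every malformed construct raises :class:`ModelFormatError` with the
    line number of the offending line.
    """
    nodes: List[NodeDef] = []
    node_names = set()
    reactions: List[Reaction] = []
    metadata: List[Tuple[str, str]] = []
    current: Optional[Tuple[str, float, int, List[Participant]]] = None

    def close_current() -> None:
        nonlocal current
        if current is None:
            return
        name, rate, lineno, parts = current
        if not parts:
            raise ModelFormatError(f"reaction {name} has no participants", lineno)
        reactions.append(Reaction(name, rate, tuple(parts)))
        current = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        head = tokens[0].lower()
        if head == "meta":
            if len(tokens) < 3:
                raise ModelFormatError("meta needs a key and a value", lineno)
            metadata.append((tokens[1], " ".join(tokens[2:])))
        elif head == "node":
            close_current()
            if len(tokens) != 3:
                raise ModelFormatError(
                    "node declaration needs a name and an initial value", lineno
                )
            name = tokens[1]
            if name in node_names:
                raise ModelFormatError(f"duplicate node {name!r}", lineno)
            try:
                init = float(tokens[2])
            except ValueError:
                raise ModelFormatError(
                    f"initial value {tokens[2]!r} is not a number", lineno
                )
            if not 0.0 <= init <= 1.0:
                raise ModelFormatError(
                    f"initial value {init} outside [0, 1]", lineno
                )
            node_names.add(name)
            nodes.append(NodeDef(name, init))
        elif head == "reaction":
            close_current()
            if len(tokens) != 3:
                raise ModelFormatError(
                    "reaction header needs a name and a rate coefficient", lineno
                )
            name = tokens[1]
            if any(r.name == name for r in reactions):
                raise ModelFormatError(f"duplicate reaction {name!r}", lineno)
            try:
                rate = float(tokens[2])
            except ValueError:
                raise ModelFormatError(
                    f"rate coefficient {tokens[2]!r} is not a number", lineno
                )
            if rate < 0:
                raise ModelFormatError(f"rate coefficient {rate} is negative", lineno)
            current = (name, rate, lineno, [])
        elif head in ROLES:
            if current is None:
                raise ModelFormatError(
                    f"participant line outside a reaction block: {line!r}", lineno
                )
            if len(tokens) < 2:
                raise ModelFormatError("participant line needs a node name", lineno)
            target = tokens[1]
            if target not in node_names:
                raise ModelFormatError(
                    f"participant references undeclared node {target!r}", lineno
                )
            rule = _parse_rule(tokens[2:], lineno)
            current[3].append(Participant(head, target, rule))
        else:
            raise ModelFormatError(f"unknown keyword {tokens[0]!r}", lineno)

    close_current()
    if not nodes:
        raise ModelFormatError("no nodes defined")
    return ModelSpec(tuple(nodes), tuple(reactions), tuple(metadata))


def serialize_model(model: ModelSpec) -> str:
    """Emit canonical dialect text (stable ordering, single spaces, LF)."""
    lines: List[str] = []
    for key, value in model.metadata:
        lines.append(f"meta {key} {value}")
    if model.metadata:
        lines.append("")
    for n in model.nodes:
        lines.append(f"node {n.name} {n.initial_value!r}")
    for r in model.reactions:
        lines.append("")
        lines.append(f"Reaction {r.name} {r.rate_coefficient!r}")
        for p in r.participants:
            rule = " ".join(str(v) for v in p.rule.outputs)
            lines.append(f"{p.role} {p.node} {rule}")
    return "\n".join(lines) + "\n"


def count_structure(model: ModelSpec) -> Tuple[int, int, int]:
    """(n_nodes, n_reactions, n_rule_lines): one rule line per participant."""
    n_rules = sum(len(r.participants) for r in model.reactions)
    return (len(model.nodes), len(model.reactions), n_rules)


def _participant_sign(p: Participant) -> int:
    """+1, -1 or 0 (ambiguous) influence of the participant on the rate."""
    if p.rule.is_nondecreasing() and not p.rule.is_nonincreasing():
        return 1
    if p.rule.is_nonincreasing() and not p.rule.is_nondecreasing():
        return -1
    if p.rule.is_nondecreasing() and p.rule.is_nonincreasing():
        return 0  # constant rule: no influence of the node on the rate
    return 0  # non-monotone: ambiguous


def signed_interaction_graph(
    model: ModelSpec,
) -> List[Tuple[str, str, int]]:
    """Edges (source, target, sign) of the influence network.

    One edge per (modulating participant, mass-changed node) pair within a
    reaction: the source raises the rate (per its rule monotonicity) and
    the rate raises products / lowers substrates.  Constant and
    non-monotone rules yield sign 0 (ambiguous).
    """
    edges: List[Tuple[str, str, int]] = []
    for r in model.reactions:
        changed = [
            (p.node, +1 if p.role == "pro" else -1)
            for p in r.participants
            if p.role in ("pro", "sub")
        ]
        for p in r.participants:
            rate_sign = _participant_sign(p)
            for target, stoich in changed:
                if p.role in ("pro", "sub") and p.node == target:
                    continue  # self-influence through own consumption
                edges.append((p.node, target, rate_sign * stoich))
    return edges


def interaction_digraph(model: ModelSpec) -> "nx.MultiDiGraph":
    """The signed interaction graph as a networkx multigraph."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(model.node_names)
    for src, dst, sign in signed_interaction_graph(model):
        g.add_edge(src, dst, sign=sign)
    return g
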