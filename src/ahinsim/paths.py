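"""Weighted meta paths over the annotated HIN.

A meta path template is a sequence of node types, e.g. ``P-D-M-D-P``; an
*instance* is a concrete node walk matching the template, carrying one
weight per edge, and its score S(P) is the product of those weights.  The
weights come from patient expansion graphs: for a symmetric patient-to-
patient template the first half of the edges is weighted by the source
patient's expansion and the second half by the target patient's — the only
split under which the worked 1*2*3*1 = 6 arithmetic holds when the two
patients annotate the same disease–medicine edge with different counts.
For a single-anchored prefix template (PDM, MDP) all weights come from the
anchored patient's expansion.  A path *exists* only if every traversed edge
exists in its governing expansion graph; an annotated disease–medicine edge
lacking the governing patient's key blocks the path, which is precisely how
false patient–drug associations are kept out of the similarity mass.

``S_sum(x -> y)`` is the sum of S(P) over all instances between x and y.
Exhaustive enumeration (`enumerate_paths`/`s_sum`) is the definitional
route, kept exponential-safe by the fixed short templates; `PatientProfile`
inner products compute the same quantity in sparse-linear time and are the
production route for all-pairs and top-k search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .ahin import (
    DISEASE,
    MEDICINE,
    PATIENT,
    AnnotatedHIN,
    ExpansionGraph,
    NodeRef,
    expansion,
)

__all__ = [
    "MetaPathTemplate",
    "WeightedMetaPathInstance",
    "PatientProfile",
    "UnsupportedTemplateError",
    "PDMDP",
    "path_score",
    "concatenate",
    "enumerate_paths",
    "s_sum",
    "profile_vector",
]

_VALID_RELATIONS = {("P", "D"), ("D", "P"), ("D", "M"), ("M", "D")}


class UnsupportedTemplateError(ValueError):
    """Template shape outside the supported patient-anchored family."""


@dataclass(frozen=True)
class MetaPathTemplate:
    """Type-level path template, e.g. (P, D, M, D, P)."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a template needs at least two node types")
        for a, b in zip(self.types, self.types[1:]):
            if (a, b) not in _VALID_RELATIONS:
                raise ValueError(f"invalid adjacent relation {a}-{b}")

    @classmethod
    def parse(cls, text: str) -> "MetaPathTemplate":
        """Parse the ``P-D-M-D-P`` mini-language (hyphen-separated letters)."""
        return cls(tuple(part.strip().upper() for part in text.split("-")))

    @property
    def length(self) -> int:
        """Edge count l."""
        return len(self.types) - 1

    @property
    def is_symmetric(self) -> bool:
        return self.types == self.types[::-1]

    def __str__(self) -> str:
        return "-".join(self.types)


PDMDP = MetaPathTemplate.parse("P-D-M-D-P")


@dataclass(frozen=True)
class WeightedMetaPathInstance:
    """A concrete node walk with per-edge weights; score = weight product."""

    nodes: tuple[NodeRef, ...]
    edge_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edge_weights) != len(self.nodes) - 1:
            raise ValueError("need exactly one weight per edge")
        if any(w <= 0 for w in self.edge_weights):
            raise ValueError("edge weights must be positive")

    @property
    def score(self) -> float:
        return math.prod(self.edge_weights)

    @property
    def template(self) -> MetaPathTemplate:
        return MetaPathTemplate(tuple(n.node_type for n in self.nodes))


def path_score(p: WeightedMetaPathInstance) -> float:
    """S(P): product of the relationship weights along the path."""
    return p.score


def concatenate(
    p: WeightedMetaPathInstance, q: WeightedMetaPathInstance
) -> WeightedMetaPathInstance:
    """Join two instances on their shared endpoint node.

    The score is multiplicative: S(pq) = S(p) * S(q).  A zero-edge instance
    acts as the identity.
    """
    if p.nodes[-1] != q.nodes[0]:
        raise ValueError(
            f"cannot concatenate: {p.nodes[-1]} != {q.nodes[0]} at the junction"
        )
    return WeightedMetaPathInstance(
        nodes=p.nodes + q.nodes[1:],
        edge_weights=p.edge_weights + q.edge_weights,
    )


def _governing_expansions(
    g: AnnotatedHIN, t: MetaPathTemplate, x: NodeRef, y: NodeRef
) -> list[ExpansionGraph]:
    """One expansion graph per edge of the template.

    Symmetric P...P templates of even edge count split half/half between the
    two endpoint patients; odd-length symmetric templates would need a
    middle edge governed by both keys at once and are rejected.  Otherwise a
    single P endpoint anchors every edge.
    """
    l = t.length
    if t.types[0] == PATIENT and t.types[-1] == PATIENT and t.is_symmetric:
        if l % 2 != 0:
            raise UnsupportedTemplateError(
                f"odd-length symmetric template {t}: the middle edge has no "
                "single governing patient"
            )
        ex, ey = expansion(g, x.node_id), expansion(g, y.node_id)
        return [ex] * (l // 2) + [ey] * (l // 2)
    if t.types[0] == PATIENT:
        ex = expansion(g, x.node_id)
        return [ex] * l
    if t.types[-1] == PATIENT:
        ey = expansion(g, y.node_id)
        return [ey] * l
    raise UnsupportedTemplateError(f"template {t} has no patient anchor")


def enumerate_paths(
    g: AnnotatedHIN, t: MetaPathTemplate, x: NodeRef, y: NodeRef
) -> list[WeightedMetaPathInstance]:
    """All weighted meta path instances from x to y matching template t.

    Every edge must exist in its governing expansion graph; node revisits
    are allowed (the self-path P-d-m-d-P is a legitimate instance).
    Deterministic order (lexicographic in the node walk).
    """
    if x.node_type != t.types[0] or y.node_type != t.types[-1]:
        raise ValueError(f"endpoints {x}, {y} do not match template {t}")
    if x not in g.graph or y not in g.graph:
        raise KeyError(f"node {x if x not in g.graph else y} not in network")
    governing = _governing_expansions(g, t, x, y)

    results: list[WeightedMetaPathInstance] = []

    def walk(pos: int, node: NodeRef, nodes: list[NodeRef], weights: list[float]) -> None:
        if pos == t.length:
            if node == y:
                results.append(
                    WeightedMetaPathInstance(tuple(nodes), tuple(weights))
                )
            return
        want = t.types[pos + 1]
        for nxt, w in governing[pos].neighbors(node):
            if nxt.node_type != want:
                continue
            nodes.append(nxt)
            weights.append(w)
            walk(pos + 1, nxt, nodes, weights)
            nodes.pop()
            weights.pop()

    walk(0, x, [x], [])
    results.sort(key=lambda p: p.nodes)
    return results


def s_sum(g: AnnotatedHIN, t: MetaPathTemplate, x: NodeRef, y: NodeRef) -> float:
    """Sum of S(P) over every instance of template t between x and y."""
    return sum(p.score for p in enumerate_paths(g, t, x, y))


@dataclass(frozen=True)
class PatientProfile:
    """Sparse (disease, medicine) -> weight vector for one patient.

    An entry (d, m) is present iff the patient's expansion graph contains
    the P-d edge and the annotated d-m edge; its value is the annotation
    count (P-D weight 1 times the D-M weight).  Under the P-D-M-D-P
    template the two disease positions of a path are bound independently,
    so S_sum between two patients equals the inner product of their
    *medicine-marginal* vectors: s_sum(x, y) = sum_m (sum_d w_x(d, m)) *
    (sum_d w_y(d, m)).  ``inner`` computes exactly that.
    """

    patient_id: str
    weights: dict[tuple[str, str], float]

    def medicine_margins(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (_, m), w in self.weights.items():
            out[m] = out.get(m, 0.0) + w
        return out

    def inner(self, other: "PatientProfile") -> float:
        a, b = self.medicine_margins(), other.medicine_margins()
        if len(b) < len(a):
            a, b = b, a
        return sum(w * b[m] for m, w in a.items() if m in b)

    def self_sum(self) -> float:
        return sum(w * w for w in self.medicine_margins().values())

    def __len__(self) -> int:
        return len(self.weights)


def profile_vector(g: AnnotatedHIN, x: NodeRef) -> PatientProfile:
    """The sparse profile whose inner products reproduce PDMDP S_sum."""
    if x.node_type != PATIENT:
        raise ValueError(f"profile_vector needs a patient node, got {x}")
    if x not in g.graph:
        raise KeyError(f"node {x} not in network")
    ex = expansion(g, x.node_id)
    weights: dict[tuple[str, str], float] = {}
    for d in g.diseases_of(x.node_id):
        for nbr, w in ex.neighbors(d):
            if nbr.node_type == MEDICINE:
                weights[(d.node_id, nbr.node_id)] = w
    return PatientProfile(patient_id=x.node_id, weights=weights)
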