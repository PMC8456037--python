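"""Annotated heterogeneous information network (AHIN) over patients,
diseases, and medicines.

A plain patient HIN connects P (patient), D (disease), and M (medicine)
nodes with untyped-weight links, and in doing so loses two things: how many
times a patient was hospitalized, and *which* patient induced each
disease–medicine link.  The annotated HIN fixes both by attaching
``<patient, count>`` annotations to D–M edges: the count records in how many
of that patient's admissions the disease and the drug co-occurred.  A
patient's *expansion graph* is the per-key weighted view of the network: an
annotated edge appears in patient p's expansion only if p's key is present
in its annotation (with weight equal to the count), every unannotated edge
appears with default weight 1.  This gating is what removes false
patient–drug associations: a drug linked to a shared disease only by some
*other* patient's prescriptions is unreachable in p's expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx

from .records import RecordSet, patient_histories

__all__ = [
    "NodeRef",
    "AnnotatedHIN",
    "ExpansionGraph",
    "Schema",
    "build_ahin",
    "build_plain_hin",
    "schema_of",
    "expansion",
]

PATIENT = "P"
DISEASE = "D"
MEDICINE = "M"
_TYPES = (PATIENT, DISEASE, MEDICINE)


class NodeRef(NamedTuple):
    """Typed node handle; (node_type, node_id) is unique within a network."""

    node_type: str
    node_id: str

    def __str__(self) -> str:  # used in serializations and error messages
        return f"{self.node_type}:{self.node_id}"


def patient_node(pid: str) -> NodeRef:
    return NodeRef(PATIENT, pid)


def disease_node(code: str) -> NodeRef:
    return NodeRef(DISEASE, code)


def medicine_node(code: str) -> NodeRef:
    return NodeRef(MEDICINE, code)


def _dm_key(d: NodeRef, m: NodeRef) -> tuple[NodeRef, NodeRef]:
    """Canonical (disease, medicine) ordering for an undirected D-M edge."""
    return (d, m) if d.node_type == DISEASE else (m, d)


@dataclass
class AnnotatedHIN:
    """G = (V, E, C): typed undirected graph plus D-M edge annotations.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    :class:`NodeRef` tuples; D-M edges carry an ``ann`` attribute mapping
    patient_id -> positive count.  P-D edges are unannotated and always
    weight 1 — repeat-admission information lives exclusively in the D-M
    annotation values.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -----------------------------------------------------
    def add_patient(self, pid: str) -> NodeRef:
        n = patient_node(pid)
        self.graph.add_node(n)
        return n

    def add_pd_edge(self, pid: str, disease: str) -> None:
        p, d = patient_node(pid), disease_node(disease)
        self.graph.add_node(p)
        self.graph.add_node(d)
        self.graph.add_edge(p, d, etype="PD")

    def add_dm_annotation(self, disease: str, medicine: str, pid: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("annotation values must be >= 1")
        d, m = disease_node(disease), medicine_node(medicine)
        self.graph.add_node(d)
        self.graph.add_node(m)
        if not self.graph.has_edge(d, m):
            self.graph.add_edge(d, m, etype="DM", ann={})
        ann = self.graph.edges[d, m]["ann"]
        ann[pid] = ann.get(pid, 0) + count

    # -- queries ----------------------------------------------------------
    def nodes_of_type(self, node_type: str) -> list[NodeRef]:
        return sorted(n for n in self.graph.nodes if n.node_type == node_type)

    @property
    def patients(self) -> list[str]:
        return [n.node_id for n in self.nodes_of_type(PATIENT)]

    def annotation(self, d: NodeRef, m: NodeRef) -> dict[str, int]:
        """The <key, value> entries of one D-M edge ({} if edge absent)."""
        d, m = _dm_key(d, m)
        if not self.graph.has_edge(d, m):
            return {}
        return dict(self.graph.edges[d, m].get("ann", {}))

    def annotation_length(self, d: NodeRef, m: NodeRef) -> int:
        return len(self.annotation(d, m))

    def dm_edges(self) -> list[tuple[NodeRef, NodeRef, dict[str, int]]]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            if data.get("etype") == "DM":
                d, m = _dm_key(u, v)
                out.append((d, m, dict(data.get("ann", {}))))
        out.sort(key=lambda t: (t[0], t[1]))
        return out

    def pd_edges(self) -> list[tuple[NodeRef, NodeRef]]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            if data.get("etype") == "PD":
                p, d = (u, v) if u.node_type == PATIENT else (v, u)
                out.append((p, d))
        out.sort()
        return out

    def diseases_of(self, pid: str) -> list[NodeRef]:
        p = patient_node(pid)
        if p not in self.graph:
            return []
        return sorted(n for n in self.graph.neighbors(p) if n.node_type == DISEASE)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [{"type": n.node_type, "id": n.node_id}
                      for n in sorted(self.graph.nodes)],
            "edges": [
                {"source": str(u), "target": str(v), "etype": data["etype"]}
                for u, v, data in sorted(
                    ((min(u, v), max(u, v), d) for u, v, d in self.graph.edges(data=True)),
                    key=lambda t: (t[0], t[1]),
                )
            ],
            "annotations": [
                {"disease": d.node_id, "medicine": m.node_id,
                 "entries": dict(sorted(ann.items()))}
                for d, m, ann in self.dm_edges()
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnnotatedHIN":
        doc = json.loads(text)
        g = cls()
        for n in doc["nodes"]:
            g.graph.add_node(NodeRef(n["type"], n["id"]))
        for e in doc["edges"]:
            ut, ui = e["source"].split(":", 1)
            vt, vi = e["target"].split(":", 1)
            g.graph.add_edge(NodeRef(ut, ui), NodeRef(vt, vi), etype=e["etype"])
        for a in doc["annotations"]:
            d, m = disease_node(a["disease"]), medicine_node(a["medicine"])
            g.graph.edges[d, m]["ann"] = {k: int(v) for k, v in a["entries"].items()}
        return g

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnnotatedHIN":
        return cls.from_json(Path(path).read_text())


class Schema(NamedTuple):
    """SG = (A, R, I): object types, relation types, annotated relations."""

    object_types: frozenset[str]
    relation_types: frozenset[str]
    annotated_relations: frozenset[str]


def build_ahin(rs: RecordSet) -> AnnotatedHIN:
    """Construct the patient-annotated HIN from an admission record set.

    For every admission of patient p containing diagnosis d, a P-D edge is
    ensured; for every (diagnosis d, medicine m) pair co-occurring in one
    admission, the annotation value of the D-M edge under key p is
    incremented by one.  An admission with several diagnoses credits every
    (d, m) pair — the record gives no drug-to-diagnosis attribution, so no
    attribution is invented.  Pure function of the record set.
    """
    g = AnnotatedHIN()
    for rec in rs:
        g.add_patient(rec.patient_id)
        for d in rec.diagnoses:
            g.add_pd_edge(rec.patient_id, d)
            for m in rec.medicines:
                g.add_dm_annotation(d, m, rec.patient_id, 1)
    return g


def build_plain_hin(rs: RecordSet) -> nx.Graph:
    """The classic (unannotated) HIN: the baseline construction.

    Same node set; a D-M edge exists as soon as *any* patient's admission
    contains both codes, with no record of whose.  This is the network on
    which a patient can appear linked to a drug they never received.
    """
    g = nx.Graph()
    for rec in rs:
        p = patient_node(rec.patient_id)
        g.add_node(p)
        for d_code in rec.diagnoses:
            d = disease_node(d_code)
            g.add_edge(p, d, etype="PD")
            for m_code in rec.medicines:
                g.add_edge(d, medicine_node(m_code), etype="DM")
    return g


def schema_of(g: AnnotatedHIN) -> Schema:
    """Meta-description of an AHIN: which types, relations, annotations occur."""
    types = frozenset(n.node_type for n in g.graph.nodes)
    relations = frozenset(
        data["etype"] for _, _, data in g.graph.edges(data=True)
    )
    annotated = frozenset(
        data["etype"]
        for _, _, data in g.graph.edges(data=True)
        if data.get("ann")
    )
    return Schema(types, relations, annotated)


@dataclass(frozen=True)
class ExpansionGraph:
    """One patient's weighted view of the AHIN (network expansion structure).

    ``weights`` maps an undirected edge (canonical node order) to its weight
    in this patient's graph.  Annotated edges whose annotation lacks the key
    are absent, which is exactly the false-link fix.
    """

    key: str
    weights: Mapping[tuple[NodeRef, NodeRef], float]

    def weight(self, u: NodeRef, v: NodeRef) -> float | None:
        e = (u, v) if u <= v else (v, u)
        return self.weights.get(e)

    def neighbors(self, u: NodeRef) -> list[tuple[NodeRef, float]]:
        out = []
        for (a, b), w in self.weights.items():
            if a == u:
                out.append((b, w))
            elif b == u:
                out.append((a, w))
        out.sort()
        return out


def expansion(g: AnnotatedHIN, key: str) -> ExpansionGraph:
    """Expansion graph of one patient.

    Raises ``KeyError`` if the key is not a patient node of the network.
    """
    if patient_node(key) not in g.graph:
        raise KeyError(f"unknown patient {key!r}")
    weights: dict[tuple[NodeRef, NodeRef], float] = {}
    for u, v, data in g.graph.edges(data=True):
        e = (u, v) if u <= v else (v, u)
        ann = data.get("ann")
        if data["etype"] == "DM" and ann:
            if key in ann:
                weights[e] = float(ann[key])
            # annotated edge whose annotation lacks this key: absent
        else:
            weights[e] = 1.0  # unannotated edges default to weight 1
    return ExpansionGraph(key=key, weights=weights)
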