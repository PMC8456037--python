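"""S-PathSim similarity and top-k patient retrieval.

S-PathSim normalizes the weighted path-sum between two patients by their
self path-sums::

    s(x, y) = 2 * S_sum(x -> y) / (S_sum(x -> x) + S_sum(y -> y))

which is symmetric, lies in [0, 1] (Cauchy-Schwarz on the per-path score
vectors), and is maximal at s(x, x) = 1 for any patient with at least one
qualifying path.  A pair with zero denominator — both patients pathless
under the template — scores 0, the formula being undefined there.

Three retrieval methods are provided:

* ``mbh``      — S-PathSim on the annotated HIN (template P-D-M-D-P);
* ``mbht``     — the same after the N-disease transform (N = 1 reduces to
  ``mbh`` exactly);
* ``baseline_pathsim`` — classic PathSim path *counts* on the unannotated
  HIN, retained as the comparison method; this is the network on which a
  patient picks up similarity mass through drugs they never received.

All-pairs scoring goes through a sparse patients-by-medicines matrix whose
row inner products equal S_sum, with self-sums cached; exhaustive path
enumeration remains available in :mod:`ahinsim.paths` as the oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .ahin import (
    DISEASE,
    MEDICINE,
    PATIENT,
    AnnotatedHIN,
    NodeRef,
    build_ahin,
    build_plain_hin,
    patient_node,
)
from .ndisease import apply_n_disease
from .paths import PDMDP, MetaPathTemplate, PatientProfile, profile_vector
from .records import RecordSet

__all__ = [
    "SimilarityScore",
    "RankedList",
    "s_pathsim",
    "mbh",
    "mbht",
    "baseline_pathsim",
    "search_all",
]

DEFAULT_K = 10  # top-k list length used throughout the evaluation


@dataclass(frozen=True)
class SimilarityScore:
    x: str
    y: str
    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0 + 1e-12):
            raise ValueError(f"similarity {self.s} outside [0, 1]")


@dataclass(frozen=True)
class RankedList:
    """Top-k retrieval output: (candidate, score) pairs, best first.

    Scores are non-increasing; ties are broken by ascending patient id; the
    query itself is excluded.
    """

    query: str
    entries: tuple[tuple[str, float], ...]

    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.entries)


def _normalize(cross: float, self_x: float, self_y: float) -> float:
    denom = self_x + self_y
    if denom == 0:
        return 0.0
    return 2.0 * cross / denom


def s_pathsim(
    g: AnnotatedHIN,
    x: str | NodeRef,
    y: str | NodeRef,
    t: MetaPathTemplate = PDMDP,
) -> SimilarityScore:
    """S-PathSim between two patients under a symmetric template.

    For the default P-D-M-D-P template the sparse-profile route is used;
    it is exactly equivalent to exhaustive path enumeration.
    """
    if not t.is_symmetric or t.types[0] != PATIENT:
        raise ValueError(f"S-PathSim needs a symmetric patient template, got {t}")
    xid = x.node_id if isinstance(x, NodeRef) else str(x)
    yid = y.node_id if isinstance(y, NodeRef) else str(y)
    if t.types != PDMDP.types:
        from .paths import s_sum  # enumeration fallback for other templates

        cross = s_sum(g, t, patient_node(xid), patient_node(yid))
        sx = s_sum(g, t, patient_node(xid), patient_node(xid))
        sy = s_sum(g, t, patient_node(yid), patient_node(yid))
    else:
        px = profile_vector(g, patient_node(xid))
        py = profile_vector(g, patient_node(yid))
        cross, sx, sy = px.inner(py), px.self_sum(), py.self_sum()
    if sx + sy == 0:
        warnings.warn(
            f"patients {xid!r} and {yid!r} have no qualifying paths; "
            "similarity reported as 0",
            stacklevel=2,
        )
    return SimilarityScore(x=xid, y=yid, s=_normalize(cross, sx, sy))


# ---------------------------------------------------------------------------
# batch scoring


def _margin_matrix(g: AnnotatedHIN) -> tuple[list[str], sp.csr_matrix]:
    """Patients-by-medicines matrix W with W[p, m] = sum_d annotation(d, m, p).

    Row inner products of W equal S_sum under P-D-M-D-P: each path
    x-d1-m-d2-y contributes ann(d1, m, x) * ann(d2, m, y), and summing the
    free d1, d2 independently factorizes per medicine.
    """
    patients = g.patients
    p_index = {p: i for i, p in enumerate(patients)}
    m_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for d, m, ann in g.dm_edges():
        j = m_index.setdefault(m.node_id, len(m_index))
        for pid, count in ann.items():
            rows.append(p_index[pid])
            cols.append(j)
            vals.append(float(count))
    W = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(patients), max(len(m_index), 1))
    )
    W.sum_duplicates()
    return patients, W


def _plain_count_matrix(rs: RecordSet) -> tuple[list[str], sp.csr_matrix]:
    """Patients-by-medicines PDM path-count matrix on the unannotated HIN."""
    g = build_plain_hin(rs)
    patients = sorted(n.node_id for n in g.nodes if n.node_type == PATIENT)
    diseases = sorted(n.node_id for n in g.nodes if n.node_type == DISEASE)
    medicines = sorted(n.node_id for n in g.nodes if n.node_type == MEDICINE)
    p_idx = {p: i for i, p in enumerate(patients)}
    d_idx = {d: i for i, d in enumerate(diseases)}
    m_idx = {m: i for i, m in enumerate(medicines)}
    a_rows, a_cols = [], []
    b_rows, b_cols = [], []
    for u, v, data in g.edges(data=True):
        if data["etype"] == "PD":
            p, d = (u, v) if u.node_type == PATIENT else (v, u)
            a_rows.append(p_idx[p.node_id])
            a_cols.append(d_idx[d.node_id])
        else:
            d, m = (u, v) if u.node_type == DISEASE else (v, u)
            b_rows.append(d_idx[d.node_id])
            b_cols.append(m_idx[m.node_id])
    A = sp.csr_matrix(
        (np.ones(len(a_rows)), (a_rows, a_cols)),
        shape=(len(patients), max(len(diseases), 1)),
    )
    B = sp.csr_matrix(
        (np.ones(len(b_rows)), (b_rows, b_cols)),
        shape=(max(len(diseases), 1), max(len(medicines), 1)),
    )
    return patients, (A @ B).tocsr()


def _rank_rows(
    patients: Sequence[str],
    W: sp.csr_matrix,
    queries: Sequence[str],
    k: int,
) -> dict[str, RankedList]:
    """Score each query row against all others and cut to top-k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    index = {p: i for i, p in enumerate(patients)}
    for q in queries:
        if q not in index:
            raise KeyError(f"unknown query patient {q!r}")
    self_sums = np.asarray(W.multiply(W).sum(axis=1)).ravel()
    out: dict[str, RankedList] = {}
    for q in queries:
        i = index[q]
        cross = np.asarray((W @ W[i].T).todense()).ravel()
        denom = self_sums + self_sums[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom > 0, 2.0 * cross / denom, 0.0)
        order = sorted(
            (p for p in patients if p != q),
            key=lambda p: (-scores[index[p]], p),
        )[:k]
        out[q] = RankedList(
            query=q, entries=tuple((p, float(scores[index[p]])) for p in order)
        )
    return out


def search_all(
    rs: RecordSet,
    method: str = "mbh",
    k: int = DEFAULT_K,
    n: int = 1,
    queries: Sequence[str] | None = None,
) -> dict[str, RankedList]:
    """Top-k lists for many queries at once (``method`` in mbh/mbht/baseline).

    Builds the network once and reuses the sparse score matrix across
    queries; defaults to querying every patient.
    """
    if method == "mbh":
        patients, W = _margin_matrix(build_ahin(rs))
    elif method == "mbht":
        if n < 1:
            raise ValueError(f"N must be >= 1, got {n}")
        patients, W = _margin_matrix(apply_n_disease(rs, n))
    elif method == "baseline":
        patients, W = _plain_count_matrix(rs)
    else:
        raise ValueError(f"unknown method {method!r}")
    if queries is None:
        queries = patients
    return _rank_rows(patients, W, queries, k)


def mbh(rs: RecordSet, query: str, k: int = DEFAULT_K) -> RankedList:
    """Top-k similar patients by S-PathSim on the annotated HIN."""
    return search_all(rs, method="mbh", k=k, queries=[query])[query]


def mbht(rs: RecordSet, query: str, k: int = DEFAULT_K, n: int = 1) -> RankedList:
    """Top-k similar patients on the N-disease-transformed annotated HIN."""
    return search_all(rs, method="mbht", k=k, n=n, queries=[query])[query]


def baseline_pathsim(rs: RecordSet, query: str, k: int = DEFAULT_K) -> RankedList:
    """Plain PathSim (path counts, unannotated HIN) comparison method."""
    return search_all(rs, method="baseline", k=k, queries=[query])[query]
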