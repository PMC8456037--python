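"""N-disease: encoding temporal order into the annotated HIN.

Disease nodes carry no notion of *when* a diagnosis happened.  The
N-disease transform borrows the n-gram idea from language modelling: each
patient's diagnoses are arranged into a time series (admission order, then
within-admission listed order), overlapping windows of width N are
collected, and the network's disease nodes are replaced by those N-gram
nodes.  Two patients then share a disease node only if they developed the
same diseases *in the same order*, so the transformed network distinguishes
"D1 then D2" from "D2 then D1".  With N = 1 the transform is the identity
(up to relabeling a code c as "[c]").

Gram labels use the canonical syntax ``[code1|code2|...]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ahin import AnnotatedHIN
from .records import AdmissionRecord, RecordSet, patient_histories

__all__ = [
    "DiseaseSequence",
    "DiseaseNGram",
    "disease_sequence",
    "n_grams",
    "apply_n_disease",
    "gram_label",
]


def gram_label(codes: Sequence[str]) -> str:
    return "[" + "|".join(codes) + "]"


@dataclass(frozen=True)
class DiseaseNGram:
    """A window of up to N consecutive disease codes from one sequence."""

    grams: tuple[str, ...]

    @property
    def label(self) -> str:
        return gram_label(self.grams)

    def __len__(self) -> int:
        return len(self.grams)


@dataclass(frozen=True)
class DiseaseSequence:
    """A patient's time-ordered diagnoses, each tagged with its admission index.

    The admission index (position of the admission in the patient's ordered
    history) lets the re-annotation step recover which hospitalizations a
    gram window spans.
    """

    patient_id: str
    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        idx = [i for _, i in self.items]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("admission indices must be non-decreasing")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.items)

    def __len__(self) -> int:
        return len(self.items)


def disease_sequence(patient_id: str, history: Sequence[AdmissionRecord]) -> DiseaseSequence:
    """Concatenate a time-ordered admission history into one disease series."""
    items = []
    for adm_idx, rec in enumerate(history):
        for code in rec.diagnoses:
            items.append((code, adm_idx))
    return DiseaseSequence(patient_id=patient_id, items=tuple(items))


def n_grams(seq: DiseaseSequence, n: int) -> list[DiseaseNGram]:
    """Overlapping sliding windows of width ``n`` over the disease series.

    A sequence shorter than ``n`` yields a single truncated gram (the whole
    sequence) so that no patient drops out of the network; an empty sequence
    yields no grams.  The count is ``max(len - n + 1, 1)`` for non-empty
    sequences.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    codes = seq.codes
    if not codes:
        return []
    if len(codes) < n:
        return [DiseaseNGram(codes)]
    return [DiseaseNGram(codes[i : i + n]) for i in range(len(codes) - n + 1)]


def _gram_windows(seq: DiseaseSequence, n: int) -> list[tuple[DiseaseNGram, frozenset[int]]]:
    """Grams paired with the set of admission indices their window covers."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    items = seq.items
    if not items:
        return []
    width = min(n, len(items))
    out = []
    for i in range(len(items) - width + 1):
        window = items[i : i + width]
        out.append(
            (DiseaseNGram(tuple(c for c, _ in window)),
             frozenset(a for _, a in window))
        )
    return out


def apply_n_disease(rs: RecordSet, n: int) -> AnnotatedHIN:
    """Build the annotated HIN whose disease nodes are N-grams.

    For each patient: a P-gram edge (weight 1) for every gram of their
    sequence, and a gram-M annotation ``<p, c>`` where ``c`` accumulates,
    over the gram's window occurrences, the number of admissions inside the
    window in which medicine M was prescribed.  An admission therefore
    contributes once per gram occurrence covering it — the same
    co-occurrence semantics as the untransformed construction, which makes
    ``apply_n_disease(rs, 1)`` graph-isomorphic to ``build_ahin(rs)`` under
    the ``c -> [c]`` relabeling.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    g = AnnotatedHIN()
    histories = patient_histories(rs)
    adm_medicines: dict[str, list[frozenset[str]]] = {
        pid: [rec.medicine_set for rec in hist] for pid, hist in histories.items()
    }
    for pid in sorted(histories):
        g.add_patient(pid)
        seq = disease_sequence(pid, histories[pid])
        for gram, adm_indices in _gram_windows(seq, n):
            g.add_pd_edge(pid, gram.label)
            for adm_idx in sorted(adm_indices):
                for med in sorted(adm_medicines[pid][adm_idx]):
                    g.add_dm_annotation(gram.label, med, pid, 1)
    return g
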