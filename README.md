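# ahinsim

Patient similarity search over admission-level electronic health records,
using an **annotated heterogeneous information network** (AHIN) and the
**S-PathSim** weighted meta-path similarity.

## The problem

Clinicians compare a patient against similar past patients to inform
treatment.  A natural data structure is a heterogeneous information network
linking patients (P), diseases (D), and medicines (M).  The plain network
loses two things, however: how many times a patient was hospitalized, and
*which* patient induced each disease–medicine link.  The second loss
creates false associations — if patients 231 and 200 share a diagnosis and
only patient 200 took perindopril, the plain network still connects
patient 231 to perindopril through the shared disease node.

The annotated HIN repairs both: each D–M edge carries `<patient, count>`
annotations recording which patient's admissions produced the link and in
how many of them.  Each patient's *expansion graph* keeps an annotated edge
only if that patient's key is present (with the count as edge weight);
unannotated edges default to weight 1.  Over a symmetric meta-path template
such as `P-D-M-D-P`, a path instance's score `S(P)` is the product of its
edge weights (first half weighted by the source patient's expansion, second
half by the target's), `S_sum(x→y)` is the sum over all instances, and

```
s(x, y) = 2 · S_sum(x→y) / (S_sum(x→x) + S_sum(y→y))
```

is the S-PathSim similarity: symmetric, in [0, 1], with s(x, x) = 1.

Temporal order is encoded by the **N-disease** transform: each patient's
diagnoses are arranged in admission order and disease nodes are replaced by
sliding N-gram nodes (`[d1|d2|...]`), so two patients share a disease node
only if they developed the same diseases in the same order.  The retrieval
methods are **MBH** (S-PathSim on the AHIN) and **MBHT** (the same after
the N-disease transform; N = 1 reduces to MBH).  Plain **PathSim** path
counts on the unannotated network are kept as the baseline.  Rankings are
scored with nDCG and half-life utility (defaults k = 10, h = 3).

## Worked example

Three admissions, two patients, one shared diagnosis:

```python
from ahinsim import table1_fixture, build_ahin, s_pathsim, mbh, baseline_pathsim
from ahinsim.ahin import disease_node, medicine_node

rs = table1_fixture()
g = build_ahin(rs)
g.annotation(disease_node("Arteriosclerotic heart disease"),
             medicine_node("Clopidogrel"))
# {'231': 2}        <- patient 231 took clopidogrel in both hospitalizations

s_pathsim(g, "231", "200")
# SimilarityScore(x='231', y='200', s=0.3333333333333333)

mbh(rs, "231")
# RankedList(query='231', entries=(('200', 0.3333333333333333),))
baseline_pathsim(rs, "231")
# RankedList(query='231', entries=(('200', 1.0),))
```

The annotated method scores the pair 1/3 — patient 231's profile
(atorvastatin ×2, bisoprolol, clopidogrel ×2) overlaps patient 200's
(aspirin, atorvastatin, perindopril) only through atorvastatin:
s = 2·2 / (9 + 3).  The baseline scores them a perfect 1.0 because, with
the single shared disease node and no per-patient gating, both patients
reach all five drugs — including drugs they never received.

From the shell, the same pipeline end to end on a synthetic cohort:

```
$ printf 'n_patients: 200\nn_clusters: 5\nseed: 7\n' > cfg.yaml
$ ahinsim simulate --config cfg.yaml -o demo
$ ahinsim search -i demo/records.csv -m mbht -N 2 -q P00000 -k 5
query_id	rank	patient_id	score
P00000	1	P00020	0.117647058824
P00000	2	P00090	0.093023255814
...
$ ahinsim search -i demo/records.csv -m mbh -o ranked.tsv
$ ahinsim evaluate --results ranked.tsv --truth demo/truth.tsv -o report.tsv
{
 "mean_ndcg": 0.8064612094735384,
 "mean_hl": 0.08818761997393564,
 "n_queries": 200, "h": 3.0, "d_policy": "mean"
}
```

`mean_ndcg` is the average rank quality of the top-10 lists against the
generator's ground-truth relevance (1 = perfectly ordered); `mean_hl` is
the average rank-discounted utility above the per-query mean relevance.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the two-patient worked-example network through the full pipeline
(records → annotated network → expansion graphs → path enumeration) and
recomputes the hand-checkable path-scoring quantities: the single
`P-D-M-D-P` instance through drug M1, the patient-to-patient path sums,
and the two prefix-template half-path scores with their multiplicative
concatenation check.  Results are written as JSON.

## Layout

- `ahinsim.records` — admission records, CSV/JSON I/O, validation
- `ahinsim.ahin` — annotated HIN construction, schema, expansion graphs
- `ahinsim.ndisease` — disease sequences, N-grams, transformed network
- `ahinsim.paths` — meta-path templates, enumeration, scoring, sparse profiles
- `ahinsim.search` — S-PathSim, MBH / MBHT / baseline top-k retrieval
- `ahinsim.ranking` — nDCG, half-life utility, batch evaluation
- `ahinsim.synth` — synthetic cohort generator with known ground truth
- `ahinsim.cli` — `ahinsim build | search | evaluate | simulate`

See `docs/methods.md` for the model details, parameter choices, and
limitations.
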