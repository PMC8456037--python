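# Methods

## Model

An admission record set is turned into an annotated heterogeneous
information network G = (V, E, C):

- **Nodes** — one P node per patient, one D node per distinct disease code,
  one M node per distinct drug code.
- **P–D edges** — present iff the patient was diagnosed with the disease in
  at least one admission; always weight 1, never annotated.  Repeat
  hospitalizations are *not* encoded here: keeping P–D at weight 1 is what
  makes the worked path arithmetic (1·w1·w2·1) hold, and the repetition
  information lives entirely in the annotations.
- **D–M annotations** — the D–M edge carries `<p, c>` where c counts the
  admissions of patient p containing both the diagnosis and the
  prescription.  An admission with several diagnoses credits *every*
  (diagnosis, medicine) pair of that admission: the record offers no
  drug-to-diagnosis attribution, so none is invented.

A patient p's **expansion graph** contains every unannotated edge at weight
1 and an annotated edge only when p's key appears in its annotation, with
the count as weight.  Path existence is evaluated in expansion graphs, so a
drug connected to a shared disease solely by other patients' prescriptions
is unreachable from p — the false-link fix.

**Weighted meta paths.**  For the symmetric template `P-D-M-D-P` the first
two edges take weights from the source patient's expansion and the last two
from the target's; this half-split is the only reading consistent with the
worked example in which both patients annotate the *same* D–M edge with
different counts.  Templates with a single P endpoint (`P-D-M`, `M-D-P`)
are weighted entirely by that patient's expansion.  Symmetric templates
with an odd edge count would need a middle edge governed by two keys at
once; they cannot arise from the P–D/D–M relation set and are rejected.
Node revisits are allowed (the self path P–d–m–d–P is an instance).

**S-PathSim.**  s(x,y) = 2·S_sum(x→y) / (S_sum(x→x) + S_sum(y→y)).
Cauchy–Schwarz on the per-path score vectors gives s ∈ [0, 1] and
s(x, x) = 1 whenever the patient has at least one qualifying path.

## Sparse fast path

Under `P-D-M-D-P` a path x–d1–m–d2–y contributes w_x(d1,m) · w_y(d2,m),
with d1 and d2 bound independently.  Summing therefore factorizes per
medicine:

    S_sum(x→y) = Σ_m ( Σ_d w_x(d,m) ) · ( Σ_d w_y(d,m) )

i.e. the inner product of the two patients' *medicine-marginal* vectors.
All-pairs and top-k retrieval build one sparse patients × medicines matrix
(scipy CSR) and score queries by row products with cached self-sums; the
exhaustive enumerator remains as the independent oracle and the two routes
are asserted equal, exactly, in the tests.  Scores are rational with small
integer numerators, so float arithmetic is exact at these magnitudes.
Note the inner product is *not* over raw (disease, medicine) entries — the
two disease positions of the template are independent — although the two
coincide whenever patients share at most one disease per medicine.

## N-disease

A patient's diagnoses are concatenated in admission order (ties between
equal admission times broken by ascending hospital ID; within-admission
order as listed).  Sliding windows of width N become the new disease
nodes, labelled `[d1|d2|...]`; labels are order-sensitive, which is the
point of the encoding.  Sequences shorter than N emit one truncated gram so
no patient leaves the network.  Re-annotation: for each window occurrence,
every admission covered by the window contributes 1 to `<p, ·>` for each
drug of that admission; with N = 1 this reproduces the untransformed
construction exactly (verified by isomorphism in the tests).  The window
re-attachment rule is a committed interpretation — an admission contributes
once per gram occurrence covering it — chosen to preserve the
co-occurrence semantics of the base construction.

## Degenerate inputs and numerical choices

- A pair with zero denominator (both patients pathless) scores 0 with a
  warning; the self-similarity of a pathless patient is likewise reported
  as 0, not 1, since the defining ratio is 0/0 there.
- Top-k ties are broken by ascending patient ID; the query is excluded
  from its own list.  k defaults to 10.
- nDCG uses log base 2 with 1-based positions; an all-zero relevance list
  scores 0 (0/0 guarded).  Half-life utility requires h > 1 (default 3);
  its default score d is the mean relevance of the evaluated candidate
  pool of each query unless fixed explicitly.
- Disease/drug codes are opaque case-sensitive strings.

## Synthetic cohorts

The generator emulates the shape of one sub-dataset of a large inpatient
registry: the preset at scale 1.0 has 13,461 patients, 946 disease types,
1,400 drug types, and targets 6.62 diagnoses per capita; the default scale
0.1 keeps the proportions at a tenth of the size.  Mechanics and defaults:

- **Clusters** (10 by default) model broad disease areas: diseases are
  partitioned round-robin into cluster vocabularies; each disease owns a
  4-drug formulary.  With probability `cluster_overlap` (0.1) a diagnosis
  or prescription leaks to the global vocabulary.
- **Admissions per patient**: 2 + Poisson(mean − 2), mean 3 — every
  patient has several records, as the registry reports, and at least two
  so a disease *sequence* exists.
- **Diagnoses per admission**: 1 + Poisson(per-capita-target / mean
  admissions − 1); within-admission duplicate draws are resampled so the
  realized per-capita mean stays on target (checked at ±0.3 by Monte
  Carlo in the tests).
- **Chronic recurrence**: with probability 0.5 a diagnosis repeats one of
  the patient's existing conditions, producing the repeat co-occurrences
  that annotations count.
- **Ground truth** relevance is the Jaccard overlap of the two patients'
  realized (disease, drug) co-occurrence sets; symmetric, 1 on the
  diagonal, higher within clusters than across by construction.

What a green test does and does not establish: the generator shares its
co-occurrence assumptions with the model (drug draws are conditioned on
the diagnosis), and its ground truth is itself a profile-overlap measure.
Passing metric tests therefore validates the pipeline's correctness and
the expected directional behaviour on cluster-structured data — not
clinical validity, and not the absolute ranking-quality numbers reported
for the real (undeposited) registry, which are out of scope.  Real EHR
features the generator does not emulate: ICD hierarchy, comorbidity
correlation structure, dosage, seasonal admission patterns.

## Known limitations

- Only patient-anchored templates are supported; `P-D-M-D-P` is the
  production template.
- The scaled evaluation samples a fixed set of 200 query patients from the
  1,346-patient preset cohort to stay inside the test-time budget.
- The annotated and baseline methods are compared directionally; on
  cluster-coherent synthetic cohorts the annotated method is expected to
  score at least as well, and the comparison table is logged rather than
  asserted, since the margin depends on generator randomness.
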