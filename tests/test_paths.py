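"""Weighted meta path scoring: enumeration oracle vs sparse profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahinsim import (
    MetaPathTemplate,
    PDMDP,
    WeightedMetaPathInstance,
    build_ahin,
    concatenate,
    enumerate_paths,
    path_score,
    profile_vector,
    s_sum,
)
from ahinsim.ahin import disease_node, medicine_node, patient_node
from ahinsim.paths import UnsupportedTemplateError

from .conftest import random_recordset

P1, P2 = patient_node("P1"), patient_node("P2")
M1, M2 = medicine_node("M1"), medicine_node("M2")
PDM = MetaPathTemplate.parse("P-D-M")
MDP = MetaPathTemplate.parse("M-D-P")


def _instance(weights, types="PDMDP"):
    nodes = tuple(patient_node(f"n{i}")._replace(node_type=t)
                  for i, t in enumerate(types))
    return WeightedMetaPathInstance(nodes=nodes, edge_weights=tuple(weights))


class TestPathScore:
    def test_worked_product(self):
        assert path_score(_instance([1, 2, 3, 1])) == 6

    def test_single_edge(self):
        assert path_score(_instance([5.0], types="PD")) == 5.0

    def test_all_default_weights(self):
        assert path_score(_instance([1, 1, 1, 1])) == 1


class TestTemplate:
    def test_parse_and_symmetry(self):
        assert PDMDP.types == ("P", "D", "M", "D", "P")
        assert PDMDP.length == 4
        assert PDMDP.is_symmetric
        assert not PDM.is_symmetric

    def test_invalid_relation(self):
        with pytest.raises(ValueError):
            MetaPathTemplate.parse("P-M")


class TestConcatenate:
    def test_scores_multiply(self, example_network):
        p3 = enumerate_paths(example_network, PDM, P1, M1)[0]
        p4 = enumerate_paths(example_network, MDP, M1, P2)[0]
        joined = concatenate(p3, p4)
        assert joined.template.types == PDMDP.types
        assert joined.score == p3.score * p4.score == 6

    def test_zero_length_identity(self):
        p = _instance([2, 3], types="PDM")
        ident = WeightedMetaPathInstance(nodes=(p.nodes[-1],), edge_weights=())
        assert concatenate(p, ident) == p

    def test_junction_mismatch(self):
        p = _instance([2, 3], types="PDM")
        q = _instance([1, 1], types="MDP")
        bad = WeightedMetaPathInstance(
            nodes=(medicine_node("other"),) + q.nodes[1:], edge_weights=q.edge_weights
        )
        with pytest.raises(ValueError, match="junction"):
            concatenate(p, bad)

    @given(
        w1=st.lists(st.integers(1, 9), min_size=1, max_size=3),
        w2=st.lists(st.integers(1, 9), min_size=1, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_multiplicativity_property(self, w1, w2):
        types1 = "PDMD"[: len(w1) + 1]
        types2 = "DMDP"[-(len(w2) + 1):]
        if types1[-1] != types2[0]:
            return  # incompatible junction types; nothing to concatenate
        p = _instance(w1, types=types1)
        q = _instance(w2, types=types2)
        q = WeightedMetaPathInstance(
            nodes=(p.nodes[-1],) + q.nodes[1:], edge_weights=q.edge_weights
        )
        assert concatenate(p, q).score == pytest.approx(p.score * q.score)


class TestEnumeration:
    def test_pdm_prefix(self, example_network):
        inst = enumerate_paths(example_network, PDM, P1, M1)
        assert len(inst) == 1 and inst[0].score == 2

    def test_mdp_prefix(self, example_network):
        inst = enumerate_paths(example_network, MDP, M1, P2)
        assert len(inst) == 1 and inst[0].score == 3

    def test_absent_edge_blocks_path(self, example_network):
        """M2 is unannotated for P2, so no path from P2 passes through it."""
        inst = enumerate_paths(example_network, PDMDP, P2, P1)
        assert all(M2 not in p.nodes for p in inst)

    def test_template_without_patient_anchor_rejected(self, example_network):
        with pytest.raises(UnsupportedTemplateError):
            enumerate_paths(example_network, MetaPathTemplate.parse("D-M-D"),
                            disease_node("D"), disease_node("D"))


class TestSSum:
    def test_worked_examples(self, example_network):
        assert s_sum(example_network, PDMDP, P1, P2) == 6
        assert s_sum(example_network, PDMDP, P2, P2) == 9
        # self-sum of P1 by exhaustive enumeration: 2^2 + 3^2
        assert s_sum(example_network, PDMDP, P1, P1) == 13

    def test_symmetry(self, example_network):
        assert s_sum(example_network, PDMDP, P1, P2) == s_sum(
            example_network, PDMDP, P2, P1
        )


class TestProfiles:
    def test_table1_profile(self, table1_network):
        prof = profile_vector(table1_network, patient_node("231"))
        assert prof.weights == {
            ("Arteriosclerotic heart disease", "Atorvastatin"): 2,
            ("Arteriosclerotic heart disease", "Bisoprolol"): 1,
            ("Arteriosclerotic heart disease", "Clopidogrel"): 2,
        }

    def test_example_profile(self, example_network):
        prof = profile_vector(example_network, P2)
        assert prof.weights == {("D", "M1"): 3}

    def test_empty_profile(self):
        from ahinsim import AdmissionRecord, RecordSet

        rs = RecordSet([AdmissionRecord("h", "p", 1, ("d",), ())])
        prof = profile_vector(build_ahin(rs), patient_node("p"))
        assert len(prof) == 0 and prof.self_sum() == 0

    def test_non_patient_rejected(self, example_network):
        with pytest.raises(ValueError):
            profile_vector(example_network, M1)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_oracle_equivalence_on_random_networks(seed):
    """Profile inner products equal exhaustive path enumeration, exactly."""
    rng = np.random.default_rng(seed)
    rs = random_recordset(rng, n_patients=3, n_diseases=3, n_drugs=3)
    g = build_ahin(rs)
    assert g.graph.number_of_nodes() <= 12
    profs = {p: profile_vector(g, patient_node(p)) for p in g.patients}
    for x in g.patients:
        for y in g.patients:
            brute = s_sum(g, PDMDP, patient_node(x), patient_node(y))
            fast = profs[x].inner(profs[y])
            assert brute == fast


def test_scores_are_positive_integers_on_integer_annotations(example_network):
    for p in enumerate_paths(example_network, PDMDP, P1, P1):
        assert p.score == int(p.score) and p.score >= 1
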