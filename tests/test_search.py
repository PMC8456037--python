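"""S-PathSim similarity and MBH / MBHT / baseline top-k retrieval."""

import numpy as np
import pytest

from ahinsim import (
    AdmissionRecord,
    MetaPathTemplate,
    RecordSet,
    baseline_pathsim,
    build_ahin,
    generate,
    mbh,
    mbht,
    s_pathsim,
    search_all,
    SynthConfig,
)

from .conftest import random_recordset


class TestSPathSim:
    def test_worked_example_six_elevenths(self, example_network):
        assert s_pathsim(example_network, "P1", "P2").s == pytest.approx(
            6 / 11, abs=1e-15
        )

    def test_self_similarity_is_one(self, example_network, table1_network):
        for g, pid in [(example_network, "P1"), (table1_network, "231")]:
            assert s_pathsim(g, pid, pid).s == 1.0

    def test_table1_score_one_third(self, table1_network):
        assert s_pathsim(table1_network, "231", "200").s == pytest.approx(
            1 / 3, abs=1e-15
        )

    def test_symmetry(self, table1_network):
        assert (
            s_pathsim(table1_network, "231", "200").s
            == s_pathsim(table1_network, "200", "231").s
        )

    def test_asymmetric_template_rejected(self, example_network):
        with pytest.raises(ValueError):
            s_pathsim(example_network, "P1", "P2", t=MetaPathTemplate.parse("P-D-M"))

    def test_pathless_pair_scores_zero_with_warning(self):
        rs = RecordSet(
            [
                AdmissionRecord("h1", "a", 1, ("d1",), ()),
                AdmissionRecord("h2", "b", 1, ("d2",), ()),
            ]
        )
        g = build_ahin(rs)
        with pytest.warns(UserWarning, match="no qualifying paths"):
            assert s_pathsim(g, "a", "b").s == 0.0
        with pytest.warns(UserWarning):
            assert s_pathsim(g, "a", "a").s == 0.0  # degenerate self-score


class TestTopK:
    def test_mbh_table1(self, table1):
        rl = mbh(table1, "231", k=10)
        assert rl.entries == (("200", pytest.approx(1 / 3)),)

    def test_k_larger_than_cohort(self, table1):
        assert len(mbh(table1, "231", k=50).entries) == 1

    def test_unknown_query(self, table1):
        with pytest.raises(KeyError):
            mbh(table1, "999")

    def test_empty_profile_query_scores_all_zero(self):
        rs = RecordSet(
            [
                AdmissionRecord("h1", "q", 1, ("d",), ()),
                AdmissionRecord("h2", "b", 1, ("d",), ("m",)),
                AdmissionRecord("h3", "a", 1, ("d",), ("m",)),
            ]
        )
        rl = mbh(rs, "q")
        assert [e for e in rl.entries] == [("a", 0.0), ("b", 0.0)]

    def test_scores_non_increasing_and_query_excluded(self):
        rng = np.random.default_rng(5)
        rs = random_recordset(rng, n_patients=6, n_diseases=4, n_drugs=4)
        for q in rs.patients:
            rl = mbh(rs, q, k=4)
            scores = [s for _, s in rl.entries]
            assert scores == sorted(scores, reverse=True)
            assert q not in rl.ids()

    def test_tie_break_ascending_patient_id(self):
        rs = RecordSet(
            [
                AdmissionRecord("h1", "q", 1, ("d",), ("m",)),
                AdmissionRecord("h2", "z", 1, ("d",), ("m",)),
                AdmissionRecord("h3", "a", 1, ("d",), ("m",)),
            ]
        )
        assert mbh(rs, "q").ids() == ("a", "z")


class TestMBHT:
    def test_n1_equals_mbh_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            rs = random_recordset(rng, n_patients=5)
            for q in rs.patients:
                assert mbht(rs, q, n=1) == mbh(rs, q)

    def test_shared_bigram_yields_nonzero_score(self):
        rs = RecordSet(
            [
                AdmissionRecord("h1", "p1", 1, ("D1", "D2", "D3"), ("M1",)),
                AdmissionRecord("h2", "p2", 1, ("D2", "D3", "D4"), ("M1",)),
            ]
        )
        rl = mbht(rs, "p1", n=2)
        assert rl.entries[0][0] == "p2" and rl.entries[0][1] > 0

    def test_reversed_order_shares_nothing_at_n2(self):
        rs = RecordSet(
            [
                AdmissionRecord("h1", "p1", 1, ("D1",), ("M1",)),
                AdmissionRecord("h2", "p1", 2, ("D2",), ("M2",)),
                AdmissionRecord("h3", "p2", 1, ("D2",), ("M3",)),
                AdmissionRecord("h4", "p2", 2, ("D1",), ("M4",)),
            ]
        )
        assert mbht(rs, "p1", n=2).entries[0][1] == 0.0

    def test_invalid_n(self, table1):
        with pytest.raises(ValueError):
            mbht(table1, "231", n=0)


class TestBaseline:
    def test_single_patient_cohort_empty_list(self):
        rs = RecordSet([AdmissionRecord("h1", "p", 1, ("d",), ("m",))])
        assert baseline_pathsim(rs, "p").entries == ()

    def test_baseline_self_maximum(self):
        rng = np.random.default_rng(3)
        rs = random_recordset(rng, n_patients=4)
        res = search_all(rs, "baseline", k=3)
        for q, rl in res.items():
            for _, s in rl.entries:
                assert 0.0 <= s <= 1.0 + 1e-12

    def test_perindopril_separates_baseline_from_mbh(self, table1):
        """On the annotated network patient 231 gains no similarity mass
        through perindopril; on the plain network the false link inflates
        the baseline score."""
        assert baseline_pathsim(table1, "231").entries[0][1] == pytest.approx(1.0)
        assert mbh(table1, "231").entries[0][1] == pytest.approx(1 / 3)


def test_property_suite_symmetry_range_selfmax():
    """Similarity is symmetric, bounded in [0,1], self-maximal, across many
    random annotated networks."""
    rng = np.random.default_rng(2024)
    import warnings

    for _ in range(60):
        rs = random_recordset(rng, n_patients=4)
        g = build_ahin(rs)
        pats = g.patients
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, x in enumerate(pats):
                sx = s_pathsim(g, x, x).s
                assert sx in (0.0, 1.0)
                for y in pats[i + 1 :]:
                    sxy = s_pathsim(g, x, y).s
                    assert 0.0 <= sxy <= 1.0
                    assert sxy == s_pathsim(g, y, x).s
                    assert sxy <= max(sx, s_pathsim(g, y, y).s) + 1e-12


def test_within_cluster_scores_exceed_cross_cluster():
    """Cohorts with little vocabulary leakage: annotated-network similarity
    is higher inside a latent cluster than across clusters."""
    rs, truth = generate(
        SynthConfig(n_patients=60, n_clusters=3, cluster_overlap=0.1, seed=9)
    )
    res = search_all(rs, "mbh", k=59)
    within, across = [], []
    for q, rl in res.items():
        for c, s in rl.entries:
            (within if truth.clusters[q] == truth.clusters[c] else across).append(s)
    assert np.mean(within) > np.mean(across)
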