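import pandas as pd
import pytest

from gibbshomology import (
    ProteinNetwork,
    aggregate,
    gene_list_overlap,
    run_cohort,
    run_patient,
)
from gibbshomology.betti import CentralityReport
from gibbshomology.expression import from_frame
from gibbshomology.filtration import GibbsHomologyNetwork


def _fake_result(sample_id, nodes, max_set):
    sub = ProteinNetwork(nodes=nodes)
    ghn = GibbsHomologyNetwork(
        sample_id=sample_id, subgraph=sub, energy={n: 0.0 for n in nodes}, threshold=32
    )
    rep = CentralityReport(
        betti_total=0, centrality={n: 0 for n in nodes}, max_value=0, max_set=set(max_set)
    )
    return ghn, rep


@pytest.fixture
def six_node_instance():
    # two triangles joined by a bridge; one triangle highly expressed
    net = ProteinNetwork(
        [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D"), ("D", "E"), ("E", "F"), ("F", "D")]
    )
    df = pd.DataFrame(
        {
            "p1": [100.0, 90.0, 95.0, 10.0, 5.0, 1.0],
            "p2": [100.0, 90.0, 95.0, 10.0, 5.0, 1.0],
        },
        index=["A", "B", "C", "D", "E", "F"],
    )
    return net, from_frame(df)


class TestRunPatient:
    def test_composition_yields_k_node_subnetwork(self, six_node_instance):
        net, table = six_node_instance
        ghn, rep = run_patient(net, table, "p1", k=4)
        assert len(ghn.subgraph) == 4
        assert {"A", "B", "C"} <= ghn.subgraph.nodes
        assert rep.max_set <= ghn.subgraph.nodes

    def test_identical_samples_identical_outputs(self, six_node_instance):
        net, table = six_node_instance
        g1, r1 = run_patient(net, table, "p1", k=4)
        g2, r2 = run_patient(net, table, "p2", k=4)
        assert g1.subgraph == g2.subgraph
        assert r1.centrality == r2.centrality and r1.max_set == r2.max_set

    def test_errors_annotated_with_sample_id(self, six_node_instance):
        net, table = six_node_instance
        with pytest.raises(ValueError, match="p1"):
            run_patient(net, table, "p1", k=0)


class TestAggregate:
    def test_pareto_counts_full_equivalence_sets(self):
        results = {
            "s1": _fake_result("s1", ["UBC"], {"UBC"}),
            "s2": _fake_result("s2", ["UBC", "RPS11"], {"UBC", "RPS11"}),
            "s3": _fake_result("s3", ["HUWE1"], {"HUWE1"}),
        }
        agg = aggregate(results)
        assert agg.pareto == {"UBC": 2, "HUWE1": 1, "RPS11": 1}
        assert sum(agg.pareto.values()) == 4 > agg.n_samples

    def test_presence_counts_membership(self):
        results = {
            f"s{i}": _fake_result(f"s{i}", ["RPS6", f"G{i}"], {f"G{i}"})
            for i in range(3)
        }
        agg = aggregate(results)
        assert agg.presence["RPS6"] == 3

    def test_single_sample_pareto_is_max_set_indicator(self):
        agg = aggregate({"s1": _fake_result("s1", ["A", "B"], {"A", "B"})})
        assert agg.pareto == {"A": 1, "B": 1}

    def test_pareto_never_exceeds_presence(self, six_node_instance):
        net, table = six_node_instance
        agg = run_cohort(net, table, k=4)
        for s, c in agg.pareto.items():
            assert c <= agg.presence[s]

    def test_permutation_invariance(self):
        results = {
            "s1": _fake_result("s1", ["A"], {"A"}),
            "s2": _fake_result("s2", ["B"], {"B"}),
        }
        flipped = {k: results[k] for k in reversed(list(results))}
        a, b = aggregate(results), aggregate(flipped)
        assert a.pareto == b.pareto and a.presence == b.presence

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate({})


class TestGeneListOverlap:
    @pytest.fixture
    def cohort(self):
        return aggregate(
            {
                "s1": _fake_result("s1", ["UBC", "RPS6"], {"UBC"}),
                "s2": _fake_result("s2", ["RPS6", "HSPA8"], {"RPS6"}),
            }
        )

    def test_all_nodes_scope(self, cohort):
        assert gene_list_overlap(cohort, {"UBC", "TP53"}) == {"UBC"}

    def test_max_only_scope(self, cohort):
        assert gene_list_overlap(cohort, {"HSPA8", "RPS6"}, scope="max_only") == {"RPS6"}

    def test_disjoint_list_empty(self, cohort):
        assert gene_list_overlap(cohort, {"TP53", "MYC"}) == set()

    def test_list_equal_to_union_returns_union(self, cohort):
        union = {"UBC", "RPS6", "HSPA8"}
        assert gene_list_overlap(cohort, union) == union

    def test_case_insensitive(self, cohort):
        assert gene_list_overlap(cohort, {"ubc"}) == {"UBC"}

    def test_empty_list_rejected(self, cohort):
        with pytest.raises(ValueError):
            gene_list_overlap(cohort, set())
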