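"""Ontology parsing, simUI, PAM clustering, silhouette and network export."""

import io
import itertools
import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from conftest import TOY_OBO
from pdzscreen import gocluster, synthetic
from pdzscreen.errors import (FormatError, IntegrityError, ProcessingError,
                              UsageError, ValidationError)
from pdzscreen.gocluster import (ClusterSolution, DissimilarityMatrix,
                                 cluster_network, dissimilarity_matrix,
                                 induced_terms, label_cluster, pam, parse_obo,
                                 read_gaf, select_k, silhouette_widths,
                                 simui_similarity, term_information_content,
                                 write_network)


def random_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix([f"p{i}" for i in range(n)], d)


def exhaustive_pam_cost(d, k):
    n = d.shape[0]
    return min(d[:, list(c)].min(axis=1).sum()
               for c in itertools.combinations(range(n), k))


class TestParseObo:
    def test_toy_parse(self, toy_dag):
        assert len(toy_dag) == 4
        assert toy_dag.graph.number_of_edges() == 3
        assert toy_dag.roots == {"BP": "GO:0000001"}

    def test_obsolete_skipped(self, caplog):
        text = TOY_OBO + "\n[Term]\nid: GO:0000099\nname: gone\n" \
            "namespace: biological_process\nis_obsolete: true\n"
        with caplog.at_level("WARNING"):
            dag = parse_obo(io.StringIO(text))
        assert "GO:0000099" not in dag
        assert "obsolete" in caplog.text

    def test_cycle_rejected(self):
        text = ("format-version: 1.2\nontology: cyc\n\n"
                "[Term]\nid: GO:1\nname: a\nnamespace: biological_process\n"
                "is_a: GO:2 ! b\n\n"
                "[Term]\nid: GO:2\nname: b\nnamespace: biological_process\n"
                "is_a: GO:1 ! a\n")
        with pytest.raises(IntegrityError, match="cycle"):
            parse_obo(io.StringIO(text))

    def test_generator_roundtrip_topology(self):
        cfg = synthetic.GoSimConfig(seed=5)
        corpus = synthetic.simulate_go_corpus(cfg)
        dag = gocluster.parse_obo(io.StringIO(corpus.obo_text))
        all_terms = {t for terms in corpus.group_terms.values() for t in terms}
        assert set(dag.graph.nodes) == all_terms | {dag.roots["BP"]}
        assert nx.is_directed_acyclic_graph(dag.graph)


class TestReadGaf:
    @staticmethod
    def gaf(rows):
        body = "\n".join("\t".join(r) for r in rows)
        return io.StringIO("!gaf-version: 2.1\n" + body + "\n")

    @staticmethod
    def row(pid, term, qualifier="", aspect="P"):
        return ["DB", pid, pid, qualifier, term, "REF", "IEA", "", aspect,
                pid, "", "protein", "taxon:9606", "20111108", "DB", "", ""]

    def test_direct_parse(self, toy_dag):
        ann = read_gaf(self.gaf([
            self.row("P1", "GO:0000002"), self.row("P1", "GO:0000004"),
            self.row("P2", "GO:0000003"),
        ]), toy_dag)
        assert ann.proteins("BP") == ["P1", "P2"]
        assert ann.terms("P1", "BP") == {"GO:0000002", "GO:0000004"}

    def test_not_qualifier_dropped(self, toy_dag):
        ann = read_gaf(self.gaf([self.row("P1", "GO:0000002", qualifier="NOT")]),
                       toy_dag)
        assert ann.proteins("BP") == []

    def test_unknown_term_dropped(self, toy_dag, caplog):
        with caplog.at_level("WARNING"):
            ann = read_gaf(self.gaf([self.row("P1", "GO:9999999")]), toy_dag)
        assert ann.proteins("BP") == []
        assert "unknown term" in caplog.text

    def test_malformed_fraction_enforced(self, toy_dag):
        rows = [self.row("P1", "GO:0000002")] + [["broken", "row"]] * 3
        with pytest.raises(FormatError):
            read_gaf(self.gaf(rows), toy_dag)


class TestInducedAndSimui:
    def test_root_only(self, toy_dag, toy_annotations):
        assert induced_terms("Proot", "BP", toy_dag, toy_annotations) == \
            {"GO:0000001"}

    def test_chain_closure(self, toy_dag, toy_annotations):
        assert induced_terms("P1", "BP", toy_dag, toy_annotations) == \
            {"GO:0000004", "GO:0000002", "GO:0000001"}

    def test_unannotated_rejected(self, toy_dag, toy_annotations):
        with pytest.raises(ValidationError):
            induced_terms("nobody", "BP", toy_dag, toy_annotations)

    def test_simui_hand_value(self, toy_dag, toy_annotations):
        # induced sets {C,A,R} and {B,R}: intersection {R}, union 4 terms
        assert simui_similarity("P1", "P2", "BP", toy_dag, toy_annotations) \
            == pytest.approx(0.25)

    def test_closure_matches_bruteforce_oracle(self):
        corpus = synthetic.simulate_go_corpus(synthetic.GoSimConfig(seed=9))
        dag = gocluster.parse_obo(io.StringIO(corpus.obo_text))
        ann = gocluster.read_gaf(io.StringIO(corpus.gaf_text), dag)

        parents = {}
        for child, parent, key in dag.graph.edges(keys=True):
            if key in ("is_a", "part_of"):
                parents.setdefault(child, set()).add(parent)

        def brute_closure(terms):
            closed = set(terms)
            while True:
                grown = closed | {p for t in closed for p in parents.get(t, ())}
                if grown == closed:
                    return closed
                closed = grown

        for pid in ann.proteins("BP"):
            assert induced_terms(pid, "BP", dag, ann) == \
                brute_closure(ann.terms(pid, "BP"))

    def test_simui_matches_set_ratio_oracle(self):
        corpus = synthetic.simulate_go_corpus(synthetic.GoSimConfig(seed=10))
        dag = gocluster.parse_obo(io.StringIO(corpus.obo_text))
        ann = gocluster.read_gaf(io.StringIO(corpus.gaf_text), dag)
        prots = ann.proteins("BP")
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.choice(prots, 2)
            ia = induced_terms(a, "BP", dag, ann)
            ib = induced_terms(b, "BP", dag, ann)
            expected = len(ia & ib) / len(ia | ib)
            got = simui_similarity(a, b, "BP", dag, ann)
            assert abs(got - expected) <= 1e-12
            assert got == simui_similarity(b, a, "BP", dag, ann)
            assert 0.0 <= got <= 1.0


class TestDissimilarityMatrix:
    def test_definition_and_invariants(self, toy_dag, toy_annotations):
        mat = dissimilarity_matrix(["P1", "P2", "Proot"], "BP", toy_dag,
                                   toy_annotations)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)
        for i, a in enumerate(mat.ids):
            for j, b in enumerate(mat.ids):
                if i < j:
                    assert mat.values[i, j] == pytest.approx(
                        1.0 - simui_similarity(a, b, "BP", toy_dag,
                                               toy_annotations))

    def test_star_closed_form(self):
        """Root plus one unique leaf per protein: all off-diagonal
        d = 1 - 1/3."""
        lines = ["format-version: 1.2", "ontology: star", "",
                 "[Term]", "id: GO:0000001", "name: root",
                 "namespace: biological_process", ""]
        ann = gocluster.AnnotationSet()
        for i in range(2, 7):
            lines += ["[Term]", f"id: GO:{i:07d}", f"name: leaf{i}",
                      "namespace: biological_process",
                      "is_a: GO:0000001 ! root", ""]
            ann.add(f"P{i}", "BP", f"GO:{i:07d}")
        dag = parse_obo(io.StringIO("\n".join(lines)))
        mat = dissimilarity_matrix([f"P{i}" for i in range(2, 7)], "BP",
                                   dag, ann)
        off = mat.values[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0 - 1.0 / 3.0)

    def test_duplicate_protein_zero_distance(self, toy_dag):
        ann = gocluster.AnnotationSet()
        for pid in ("A", "Acopy", "B"):
            ann.add(pid, "BP", "GO:0000004" if pid != "B" else "GO:0000003")
        mat = dissimilarity_matrix(["A", "Acopy", "B"], "BP", toy_dag, ann)
        assert mat.values[0, 1] == 0.0

    def test_unannotated_excluded_and_minimum(self, toy_dag, toy_annotations):
        with pytest.raises(ProcessingError):
            dissimilarity_matrix(["P1", "P2", "ghost"], "BP", toy_dag,
                                 toy_annotations)


class TestPam:
    def test_k_equals_n(self):
        rng = np.random.default_rng(1)
        mat = random_matrix(rng, 5)
        sol = pam(mat, 5)
        assert sol.cost == 0.0
        assert sorted(sol.medoids) == mat.ids

    def test_k_one_is_total_distance_minimiser(self):
        rng = np.random.default_rng(2)
        mat = random_matrix(rng, 7)
        sol = pam(mat, 1)
        expected = mat.ids[int(np.argmin(mat.values.sum(axis=1)))]
        assert sol.medoids == [expected]
        assert sol.cost == pytest.approx(mat.values.sum(axis=1).min())

    def test_never_beats_and_mostly_matches_exhaustive_oracle(self):
        """BUILD+SWAP cost is bounded below by the exhaustive medoid
        optimum and reaches it on the vast majority of small random
        instances (single-swap descent has rare local optima)."""
        rng = np.random.default_rng(42)
        matches = 0
        for _ in range(200):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            mat = random_matrix(rng, n)
            sol = pam(mat, k)
            best = exhaustive_pam_cost(mat.values, k)
            assert sol.cost >= best - 1e-9
            matches += abs(sol.cost - best) < 1e-9
        assert matches >= 180

    def test_matches_reference_pam_on_trapped_instance(self):
        """On an instance where single-swap descent provably cannot reach
        the global optimum, our converged cost equals the one R's
        cluster::pam reports (0.7703799; the global optimum is 0.7079106)."""
        d = np.array([
            [0.0, 0.1115968, 0.18429602, 0.50194672, 0.62088186, 0.35662812, 0.81833961],
            [0.1115968, 0.0, 0.33476371, 0.55172547, 0.81649726, 0.76984539, 0.52240966],
            [0.18429602, 0.33476371, 0.0, 0.15783067, 0.78066831, 0.62153652, 0.72058637],
            [0.50194672, 0.55172547, 0.15783067, 0.0, 0.58139076, 0.27613564, 0.3650703],
            [0.62088186, 0.81649726, 0.78066831, 0.58139076, 0.0, 0.13588211, 0.49900511],
            [0.35662812, 0.76984539, 0.62153652, 0.27613564, 0.13588211, 0.0, 0.91502672],
            [0.81833961, 0.52240966, 0.72058637, 0.3650703, 0.49900511, 0.91502672, 0.0],
        ])
        mat = DissimilarityMatrix([f"p{i}" for i in range(7)], d)
        sol = pam(mat, 3)
        assert sol.cost == pytest.approx(0.7703799, abs=1e-6)
        # no single medoid/non-medoid exchange improves the converged state
        idx = {p: i for i, p in enumerate(mat.ids)}
        med = [idx[m] for m in sol.medoids]
        for mi in range(3):
            for h in range(7):
                if h in med:
                    continue
                trial = med[:mi] + [h] + med[mi + 1:]
                assert d[:, trial].min(axis=1).sum() >= sol.cost - 1e-12

    def test_deterministic_and_medoids_self_assigned(self):
        rng = np.random.default_rng(3)
        mat = random_matrix(rng, 10)
        s1, s2 = pam(mat, 3), pam(mat, 3)
        assert s1.medoids == s2.medoids and s1.assignment == s2.assignment
        for ci, m in enumerate(s1.medoids):
            assert s1.assignment[m] == ci

    def test_cost_recomputes_from_matrix(self):
        rng = np.random.default_rng(4)
        mat = random_matrix(rng, 9)
        sol = pam(mat, 3)
        idx = {p: i for i, p in enumerate(mat.ids)}
        med = [idx[m] for m in sol.medoids]
        assert sol.cost == pytest.approx(
            mat.values[:, med].min(axis=1).sum())

    def test_k_out_of_range(self):
        rng = np.random.default_rng(5)
        with pytest.raises(UsageError):
            pam(random_matrix(rng, 4), 5)


class TestSilhouette:
    D4 = np.array([
        [0.0, 0.1, 0.9, 0.8],
        [0.1, 0.0, 0.7, 0.6],
        [0.9, 0.7, 0.0, 0.2],
        [0.8, 0.6, 0.2, 0.0],
    ])

    def test_hand_worked_four_points(self):
        s = silhouette_widths(self.D4, np.array([0, 0, 1, 1]))
        expected = [(0.85 - 0.1) / 0.85, (0.65 - 0.1) / 0.65,
                    (0.8 - 0.2) / 0.8, (0.7 - 0.2) / 0.7]
        assert np.allclose(s, expected)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        d = random_matrix(rng, 12).values
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        ours = silhouette_widths(d, labels)
        theirs = silhouette_samples(d, labels, metric="precomputed")
        assert np.allclose(ours, theirs)

    def test_singleton_gets_zero(self):
        s = silhouette_widths(self.D4, np.array([0, 0, 0, 1]))
        assert s[3] == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(7)
        d = random_matrix(rng, 15).values
        labels = rng.integers(0, 3, 15)
        s = silhouette_widths(d, labels)
        assert np.all(s >= -1.0) and np.all(s <= 1.0)


class TestSelectK:
    def test_two_separated_pairs(self):
        d = np.full((4, 4), 0.95)
        d[0, 1] = d[1, 0] = 0.02
        d[2, 3] = d[3, 2] = 0.02
        np.fill_diagonal(d, 0.0)
        mat = DissimilarityMatrix(list("abcd"), d)
        best_k, sol, profile = select_k(mat, 2, 3)
        assert best_k == 2
        assert sol.avg_silhouette > 0.9

    def test_invalid_range(self):
        rng = np.random.default_rng(8)
        with pytest.raises(UsageError):
            select_k(random_matrix(rng, 5), 2, 10)

    def test_tie_prefers_smaller_k(self):
        # four equidistant points: silhouettes tie, smaller k must win
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        mat = DissimilarityMatrix(list("abcd"), d)
        best_k, _sol, profile = select_k(mat, 2, 3)
        ties = [k for k, v in profile.items()
                if v == max(profile.values())]
        assert best_k == min(ties)


class TestNetwork:
    @staticmethod
    def three_point_matrix(d01, d02, d12):
        d = np.array([[0.0, d01, d02], [d01, 0.0, d12], [d02, d12, 0.0]])
        return DissimilarityMatrix(["a", "b", "c"], d)

    def test_threshold_excludes_all(self):
        mat = self.three_point_matrix(0.5, 0.5, 0.5)
        net = cluster_network(mat, pam(mat, 1), "CC")
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 3

    def test_strictly_above_threshold_dropped(self):
        """0.4 is kept (the rule removes scores above the threshold),
        0.41 is dropped."""
        mat = self.three_point_matrix(0.1, 0.4, 0.41)
        net = cluster_network(mat, pam(mat, 1), "MF")
        kept = {frozenset(e) for e in net.edges}
        assert kept == {frozenset({"a", "b"}), frozenset({"a", "c"})}

    def test_one_medoid_per_cluster(self):
        rng = np.random.default_rng(9)
        mat = random_matrix(rng, 10)
        sol = pam(mat, 3)
        net = cluster_network(mat, sol, "BP")
        for ci in range(3):
            medoids = [n for n, d in net.nodes(data=True)
                       if d["cluster"] == ci and d["is_medoid"]]
            assert len(medoids) == 1

    def test_unknown_aspect(self):
        rng = np.random.default_rng(10)
        mat = random_matrix(rng, 4)
        with pytest.raises(UsageError):
            cluster_network(mat, pam(mat, 1), "XX")

    def test_graphml_and_sif_written(self, tmp_path):
        rng = np.random.default_rng(11)
        mat = random_matrix(rng, 6)
        net = cluster_network(mat, pam(mat, 2), "BP")
        graphml, sif = write_network(net, tmp_path)
        back = nx.read_graphml(graphml)
        assert set(back.nodes) == set(net.nodes)
        assert back.number_of_edges() == net.number_of_edges()
        sif_edges = {frozenset((a, b)) for a, _r, b in
                     (line.split("\t") for line in sif.read_text().splitlines()
                      if "\t" in line)}
        assert sif_edges == {frozenset(e) for e in net.edges}


class TestLabelCluster:
    def test_single_direct_term(self, toy_dag, toy_annotations):
        sol = ClusterSolution(k=1, medoids=["P1"],
                              assignment={"P1": 0, "P2": 0, "Proot": 0},
                              cost=0.0, avg_silhouette=0.0)
        assert label_cluster(sol, 0, toy_dag, toy_annotations, "BP") == "C"

    def test_root_loses_to_leaf(self, toy_dag):
        ann = gocluster.AnnotationSet()
        ann.add("M", "BP", "GO:0000001")
        ann.add("M", "BP", "GO:0000004")
        ann.add("Q", "BP", "GO:0000003")
        sol = ClusterSolution(k=1, medoids=["M"], assignment={"M": 0, "Q": 0},
                              cost=0.0, avg_silhouette=0.0)
        assert label_cluster(sol, 0, toy_dag, ann, "BP") == "C"

    def test_ic_matches_counting_oracle(self, toy_dag, toy_annotations):
        proteins = ["P1", "P2", "Proot"]
        ic = term_information_content(
            ["GO:0000001", "GO:0000004", "GO:0000003"], "BP", toy_dag,
            toy_annotations, proteins)
        # root in all 3 induced sets, C in 1/3, B in 1/3
        assert ic["GO:0000001"] == pytest.approx(0.0)
        assert ic["GO:0000004"] == pytest.approx(-math.log(1 / 3))
        assert ic["GO:0000003"] == pytest.approx(-math.log(1 / 3))
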