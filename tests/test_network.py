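import networkx as nx
import numpy as np
import pytest

from mznet import (
    ConsensusNode,
    MolecularNetwork,
    NetworkEdge,
    NetworkParams,
    Peak,
    SampleRecord,
    SimilarityParams,
    build_network,
    cosine,
    export_network,
    library_search,
    mutual_topk_filter,
    score_all_pairs,
)
from conftest import make_spectrum
from oracles import bf_mutual_topk, random_spectrum


def node_from(spectrum, node_id, samples=("s1",)):
    return ConsensusNode(
        node_id=node_id,
        precursor_mz=spectrum.precursor_mz,
        peaks=spectrum.peaks,
        member_spectrum_ids=[f"m{node_id}"],
        sample_presence={s: 1 for s in samples},
        strain_presence=set(samples),
    )


class TestScoreAllPairs:
    def test_identical_nodes_edge(self):
        s = make_spectrum(range(100, 900, 100), precursor=1000.0)
        nodes = [node_from(s, 0), node_from(s, 1)]
        (edge,) = score_all_pairs(nodes)
        assert edge.cosine == pytest.approx(1.0)
        assert edge.matched_peaks == 8
        assert edge.mass_diff == 0.0
        assert (edge.node_a, edge.node_b) == (0, 1)

    def test_matched_peak_floor_rejects(self):
        # only 3 shared fragments: high cosine but below the matched-peak floor
        a = make_spectrum([100.0, 200.0, 300.0], precursor=400.0)
        b = make_spectrum([100.0, 200.0, 300.0], precursor=400.0)
        nodes = [node_from(a, 0), node_from(b, 1)]
        assert (
            cosine(a, b).score == pytest.approx(1.0)
            and score_all_pairs(nodes) == []
        )

    def test_candidates_match_bruteforce_double_loop(self, rng):
        sp = SimilarityParams()
        np_ = NetworkParams()
        nodes = [
            node_from(random_spectrum(rng, n_peaks=(8, 15)), i) for i in range(20)
        ]
        got = {(e.node_a, e.node_b) for e in score_all_pairs(nodes, np_, sp)}
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                res = cosine(
                    nodes[i].consensus_spectrum(), nodes[j].consensus_spectrum(), sp
                )
                if res.score >= np_.min_cosine and res.matched_peaks >= np_.min_matched_peaks:
                    expected.add((i, j))
        assert got == expected


def _edge(a, b, score):
    return NetworkEdge(
        node_a=min(a, b), node_b=max(a, b), cosine=score, matched_peaks=6, mass_diff=0.0
    )


class TestMutualTopK:
    def test_low_degree_edges_all_kept(self):
        cands = [_edge(0, i, 0.9 - 0.01 * i) for i in range(1, 6)]
        assert mutual_topk_filter(cands, NetworkParams(top_k=10)) == cands

    def test_hub_drops_low_ranked_leaf(self):
        # hub 0 has 15 neighbours; leaf 12 ranks 12th for the hub
        cands = [_edge(0, i, 1.0 - 0.01 * i) for i in range(1, 16)]
        kept = mutual_topk_filter(cands, NetworkParams(top_k=10))
        kept_leaves = {e.node_b for e in kept}
        assert kept_leaves == set(range(1, 11))
        assert 12 not in kept_leaves

    def test_rank_ties_at_boundary_included(self):
        cands = [_edge(0, i, 0.9) for i in range(1, 4)]
        kept = mutual_topk_filter(cands, NetworkParams(top_k=2))
        assert len(kept) == 3  # all tied at the k-th position survive

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(5, 25))
            cands = []
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.4:
                        cands.append(_edge(a, b, float(rng.uniform(0.7, 1.0))))
            k = int(rng.integers(1, 6))
            got = mutual_topk_filter(cands, NetworkParams(top_k=k))
            expected = bf_mutual_topk(cands, k)
            assert sorted((e.node_a, e.node_b) for e in got) == sorted(
                (e.node_a, e.node_b) for e in expected
            )

    def test_idempotent_on_own_output(self, rng):
        cands = [
            _edge(a, b, float(rng.uniform(0.7, 1.0)))
            for a in range(10)
            for b in range(a + 1, 10)
            if rng.random() < 0.5
        ]
        np_ = NetworkParams(top_k=3)
        once = mutual_topk_filter(cands, np_)
        assert mutual_topk_filter(once, np_) == once
        assert set(once) <= set(cands)

    def test_raising_min_cosine_never_adds_edges(self, rng):
        nodes = [
            node_from(random_spectrum(rng, n_peaks=(8, 15)), i) for i in range(15)
        ]
        loose = build_network(nodes, NetworkParams(min_cosine=0.5))
        tight = build_network(nodes, NetworkParams(min_cosine=0.8))
        loose_pairs = {(e.node_a, e.node_b) for e in loose.edges}
        tight_pairs = {(e.node_a, e.node_b) for e in tight.edges}
        assert tight_pairs <= loose_pairs

    def test_network_is_simple_and_undirected(self, small_run):
        edges = small_run["net"].edges
        pairs = [(e.node_a, e.node_b) for e in edges]
        assert all(a < b for a, b in pairs)
        assert len(pairs) == len(set(pairs))


class TestLibrarySearch:
    def test_identical_entry_perfect_hit(self):
        s = make_spectrum(range(100, 600, 50), precursor=700.0)
        nodes = [node_from(s, 0)]
        lib = [s.with_peaks(s.peaks)]
        hits = library_search(nodes, lib)
        (hit,) = hits[0]
        assert hit.score == pytest.approx(1.0)
        assert hit.matched_peaks == 10
        assert hit.is_best

    def test_no_entry_within_thresholds(self):
        node = node_from(make_spectrum([100, 200, 300], precursor=400.0), 0)
        lib = [make_spectrum([111, 222, 333], precursor=444.0)]
        assert library_search([node], lib) == {}

    def test_empty_library_no_hits(self):
        node = node_from(make_spectrum(range(100, 200, 10), precursor=400.0), 0)
        assert library_search([node], []) == {}

    def test_planted_matches_recovered_exactly(self, rng):
        lib = [
            random_spectrum(rng, n_peaks=(8, 14), spectrum_id=f"compound{i}")
            for i in range(50)
        ]
        planted = [3, 11, 22, 37, 49]
        nodes = [node_from(lib[i], k) for k, i in enumerate(planted)]
        hits = library_search(nodes, lib)
        assert set(hits) == set(range(5))
        for k, i in enumerate(planted):
            best = next(h for h in hits[k] if h.is_best)
            assert best.compound_name == f"compound{i}"
            assert best.score == pytest.approx(1.0)


class TestExport:
    META = [
        SampleRecord("s1", "KP1", "Scotland", "Bacillus", False),
        SampleRecord("s2", "KP2", "Antarctica", "Kocuria", False),
        SampleRecord("b1", "b1", "", "unknown", True),
    ]

    def test_empty_network(self, tmp_path):
        net = MolecularNetwork(nodes=[], edges=[])
        paths = export_network(net, self.META, tmp_path)
        assert paths["nodes"].read_text().startswith("node_id\t")
        assert len(paths["nodes"].read_text().splitlines()) == 1
        g = nx.read_graphml(paths["graphml"])
        assert g.number_of_nodes() == 0

    def test_round_trip_attributes(self, tmp_path):
        s = make_spectrum(range(100, 900, 100), precursor=1000.0)
        nodes = [
            node_from(s, 0, samples=("s1",)),
            node_from(s, 1, samples=("s2",)),
            node_from(s, 2, samples=("s1", "s2")),
        ]
        net = build_network(nodes)
        paths = export_network(net, self.META, tmp_path)
        g = nx.read_graphml(paths["graphml"])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == len(net.edges) > 0
        labels = nx.get_node_attributes(g, "group_label")
        assert labels == {"0": "Scotland", "1": "Antarctica", "2": "both"}

    def test_blank_only_node_labelled_media(self, tmp_path):
        s = make_spectrum(range(100, 900, 100), precursor=1000.0)
        nodes = [node_from(s, 0, samples=("b1",))]
        net = MolecularNetwork(nodes=nodes, edges=[])
        paths = export_network(net, self.META, tmp_path)
        row = paths["nodes"].read_text().splitlines()[1].split("\t")
        assert row[4] == "media"
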