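import json

import numpy as np
import pytest

from plasmidnet.network import PlasmidGraph, assign_clusters
from plasmidnet.scoring import (
    HitRecord,
    SampleHits,
    heatmap_matrix,
    load_sample,
    pair_score,
    plasmid_weight,
    remove_redundant,
    sample_to_dict,
    write_retention_report,
)
from plasmidnet.sketch import DistanceEdge
from plasmidnet.synthetic import generate_sample_hits


def _toy_graph(nodes_lengths, pairs):
    edges = [DistanceEdge(a, b, 500, 0.8, 0.01, 0.0) for a, b in pairs]
    g = PlasmidGraph(
        nodes=list(nodes_lengths),
        edges=edges,
        length_of=dict(nodes_lengths),
    )
    return assign_clusters(g)


def _random_graph_and_sample(rng, mode, n_nodes=12, n_edges=15, n_hits=8):
    nodes = {f"N{i:02d}": int(rng.integers(2_000, 120_000)) for i in range(n_nodes)}
    names = sorted(nodes)
    pairs = set()
    while len(pairs) < n_edges:
        a, b = rng.choice(names, size=2, replace=False)
        pairs.add(tuple(sorted((a, b))))
    graph = _toy_graph(nodes, sorted(pairs))
    hit_names = list(rng.choice(names, size=n_hits, replace=False))
    hits = {}
    for acc in hit_names:
        if mode == "mapping":
            hits[acc] = HitRecord(cov=float(rng.uniform(0.3, 1.0)))
        elif mode == "screen":
            hits[acc] = HitRecord(ids=float(rng.uniform(0.7, 1.0)))
        else:
            hits[acc] = HitRecord(idd=float(rng.uniform(0.85, 1.0)),
                                  sh=float(rng.uniform(0.2, 1.0)))
    return graph, SampleHits("random", mode, hits)


class TestLoadSample:
    def test_empty_hits(self):
        sample = load_sample({"sample": "s", "mode": "mapping", "hits": {}})
        assert sample.hits == {} and sample.mode == "mapping"

    def test_percentage_normalized_with_warning(self):
        doc = {"sample": "s", "mode": "mapping", "hits": {"A": {"cov": 95}}}
        with pytest.warns(UserWarning, match="percentage"):
            sample = load_sample(doc)
        assert sample.hits["A"].cov == pytest.approx(0.95)

    def test_missing_mode_field_is_error(self):
        doc = {"sample": "s", "mode": "dist", "hits": {"A": {"idd": 0.9}}}
        with pytest.raises(ValueError, match="sh"):
            load_sample(doc)

    def test_unknown_accession_flagged_but_retained(self):
        graph = _toy_graph({"A": 1000}, [])
        doc = {"sample": "s", "mode": "screen", "hits": {"GHOST": {"ids": 0.9}}}
        with pytest.warns(UserWarning, match="GHOST"):
            sample = load_sample(doc, graph)
        assert "GHOST" in sample.hits and sample.unknown == {"GHOST"}

    def test_round_trip_is_lossless(self):
        doc = {
            "sample": "asm", "mode": "dist",
            "hits": {"A": {"idd": 0.93, "sh": 0.41, "contig": "ctg_7"},
                     "B": {"idd": 0.99, "sh": 0.88}},
        }
        assert sample_to_dict(load_sample(doc)) == doc
        # and through actual JSON text
        assert sample_to_dict(load_sample(json.loads(json.dumps(doc)))) == doc


class TestWeights:
    @pytest.mark.parametrize(
        "hit, length, mode, expected",
        [
            (HitRecord(cov=0.0), 99_999, "mapping", 0.0),
            (HitRecord(ids=1.0), 50_000, "screen", 50_000.0),
            (HitRecord(idd=0.95, sh=0.6), 40_000, "dist", 22_800.0),
        ],
    )
    def test_examples(self, hit, length, mode, expected):
        assert plasmid_weight(hit, length, mode) == pytest.approx(expected)


class TestPairScore:
    def test_mapping_worked_example(self):
        decision = pair_score(
            HitRecord(cov=0.9), HitRecord(cov=0.8), 50_000, 40_000, "mapping"
        )
        assert decision.S == pytest.approx(13_000.0)
        assert decision.outcome == "keep_a"

    def test_identical_hits_tie(self):
        hit = HitRecord(ids=0.92)
        decision = pair_score(hit, hit, 30_000, 30_000, "screen")
        assert decision.S == 0.0 and decision.outcome == "keep_both"

    @pytest.mark.parametrize("mode", ["mapping", "screen", "dist"])
    def test_antisymmetry_on_random_pairs(self, mode):
        rng = np.random.default_rng(31)
        flip = {"keep_a": "keep_b", "keep_b": "keep_a", "keep_both": "keep_both"}
        for _ in range(300):
            if mode == "mapping":
                a, b = (HitRecord(cov=float(rng.uniform())) for _ in range(2))
            elif mode == "screen":
                a, b = (HitRecord(ids=float(rng.uniform())) for _ in range(2))
            else:
                a, b = (HitRecord(idd=float(rng.uniform()), sh=float(rng.uniform()))
                        for _ in range(2))
            la, lb = (int(rng.integers(1000, 200_000)) for _ in range(2))
            fwd = pair_score(a, b, la, lb, mode)
            rev = pair_score(b, a, lb, la, mode)
            assert fwd.S == -rev.S
            assert rev.outcome == flip[fwd.outcome]

    def test_outcome_matches_weight_sign_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(200):
            cov_a, cov_b = rng.uniform(size=2)
            la, lb = rng.integers(1000, 100_000, size=2)
            sign = np.sign(cov_a * la - cov_b * lb)
            decision = pair_score(HitRecord(cov=cov_a), HitRecord(cov=cov_b),
                                  int(la), int(lb), "mapping")
            expected = {1: "keep_a", -1: "keep_b", 0: "keep_both"}[int(sign)]
            assert decision.outcome == expected


class TestRemoveRedundant:
    def test_unlinked_hits_all_retained(self):
        graph = _toy_graph({"A": 1000, "B": 2000}, [])
        sample = SampleHits("s", "mapping",
                            {"A": HitRecord(cov=0.1), "B": HitRecord(cov=0.9)})
        retained, decisions = remove_redundant(sample, graph)
        assert retained == {"A", "B"} and decisions == []

    def test_linked_pair_keeps_heavier(self):
        graph = _toy_graph({"A": 50_000, "B": 40_000}, [("A", "B")])
        sample = SampleHits("s", "mapping",
                            {"A": HitRecord(cov=0.9), "B": HitRecord(cov=0.8)})
        retained, decisions = remove_redundant(sample, graph)
        assert retained == {"A"}
        assert decisions[0].S == pytest.approx(13_000.0)

    def test_tie_keeps_both(self):
        graph = _toy_graph({"A": 10_000, "B": 10_000}, [("A", "B")])
        sample = SampleHits("s", "screen",
                            {"A": HitRecord(ids=0.5), "B": HitRecord(ids=0.5)})
        retained, _ = remove_redundant(sample, graph)
        assert retained == {"A", "B"}

    @pytest.mark.parametrize("mode", ["mapping", "screen", "dist"])
    def test_matches_brute_force_non_loser_oracle(self, mode):
        rng = np.random.default_rng(33)
        for _ in range(30):
            graph, sample = _random_graph_and_sample(rng, mode)
            retained, _ = remove_redundant(sample, graph)
            # oracle: iterate every edge, collect hits that never lose
            weights = {
                acc: plasmid_weight(hit, graph.length_of[acc], mode)
                for acc, hit in sample.hits.items()
            }
            losers = set()
            for e in graph.edges:
                if e.accession_a in weights and e.accession_b in weights:
                    wa, wb = weights[e.accession_a], weights[e.accession_b]
                    if wa > wb:
                        losers.add(e.accession_b)
                    elif wb > wa:
                        losers.add(e.accession_a)
            assert retained == set(weights) - losers
            # survivor soundness
            adj = graph.neighbors()
            for acc in retained:
                for other in adj[acc] & set(weights):
                    assert weights[acc] >= weights[other]
            for acc in set(weights) - retained:
                assert any(weights[o] > weights[acc]
                           for o in adj[acc] & set(weights))

    def test_at_least_one_survivor_per_clique(self):
        rng = np.random.default_rng(34)
        names = [f"C{i}" for i in range(5)]
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        graph = _toy_graph({n: int(rng.integers(5000, 50_000)) for n in names}, pairs)
        sample = SampleHits(
            "s", "mapping",
            {n: HitRecord(cov=float(rng.uniform(0.2, 1.0))) for n in names},
        )
        retained, _ = remove_redundant(sample, graph)
        assert retained, "the maximum-weight hit of a clique must survive"
        weights = {n: plasmid_weight(sample.hits[n], graph.length_of[n], "mapping")
                   for n in names}
        assert max(weights, key=weights.get) in retained

    def test_dist_with_full_sharing_degenerates_to_screen(self):
        rng = np.random.default_rng(35)
        graph, screen_sample = _random_graph_and_sample(rng, "screen")
        dist_sample = SampleHits(
            screen_sample.sample_name, "dist",
            {acc: HitRecord(idd=hit.ids, sh=1.0)
             for acc, hit in screen_sample.hits.items()},
        )
        assert remove_redundant(dist_sample, graph)[0] == \
            remove_redundant(screen_sample, graph)[0]

    def test_generator_ground_truth_agrees(self, graph):
        for seed in range(5):
            doc, truth = generate_sample_hits(graph, "dist", 6, seed=seed)
            sample = load_sample(doc, graph)
            assert remove_redundant(sample, graph)[0] == truth


class TestHeatmap:
    def test_single_sample_single_row(self):
        sample = SampleHits("s1", "mapping", {"A": HitRecord(cov=0.7)})
        matrix = heatmap_matrix([sample])
        assert matrix.shape == (1, 1)
        assert matrix.loc["s1 (mapping)", "A"] == pytest.approx(0.7)

    def test_disjoint_hit_sets_give_block_zeros(self):
        s1 = SampleHits("s1", "mapping", {"A": HitRecord(cov=0.5)})
        s2 = SampleHits("s2", "screen", {"B": HitRecord(ids=0.9)})
        matrix = heatmap_matrix([s1, s2])
        assert matrix.loc["s1 (mapping)", "B"] == 0.0
        assert matrix.loc["s2 (screen)", "A"] == 0.0

    def test_matches_tabulation_oracle(self):
        rng = np.random.default_rng(36)
        graphs_samples = [_random_graph_and_sample(rng, m) for m in
                          ("mapping", "screen", "dist")]
        samples = [s for _, s in graphs_samples]
        matrix = heatmap_matrix(samples)
        columns = sorted({acc for s in samples for acc in s.hits})
        assert list(matrix.columns) == columns
        for sample in samples:
            row = f"{sample.sample_name} ({sample.mode})"
            for acc in columns:
                hit = sample.hits.get(acc)
                if hit is None:
                    expected = 0.0
                elif sample.mode == "mapping":
                    expected = hit.cov
                elif sample.mode == "screen":
                    expected = hit.ids
                else:
                    expected = hit.idd * hit.sh
                assert matrix.loc[row, acc] == pytest.approx(expected)

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix([])


class TestRetentionReport:
    def test_report_names_eliminator(self, tmp_path):
        graph = _toy_graph({"A": 50_000, "B": 40_000}, [("A", "B")])
        sample = SampleHits("s", "mapping",
                            {"A": HitRecord(cov=0.9), "B": HitRecord(cov=0.8)})
        path = tmp_path / "report.tsv"
        retained = write_retention_report(sample, graph, path)
        assert retained == {"A"}
        lines = path.read_text().splitlines()
        assert lines[0] == "accession\tweight\toutcome\teliminated_by"
        row_b = dict(zip(lines[0].split("\t"), lines[2].split("\t")))
        assert row_b["outcome"] == "dropped" and row_b["eliminated_by"] == "A"
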