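"""Pathway model: edit operations, curation log, integrity detectors."""

import numpy as np
import pytest

from psflow import Pathway, PathwayEdge, PathwayNode, ValidationError, replay_log

from conftest import build_pathway, reachability_closure


def gene(nid: str, **kw) -> PathwayNode:
    kw.setdefault("gene_ids", [f"gene_{nid}"])
    return PathwayNode(id=nid, label=nid, kind="gene", **kw)


class TestNodeEdits:
    def test_add_node_to_empty_pathway(self):
        p = Pathway("p").add_node(gene("A"))
        assert set(p.nodes) == {"A"}
        assert len(p.curation_log) == 1
        assert p.nodes["A"].provenance == "curated"

    def test_add_duplicate_id_rejected(self):
        p = Pathway("p").add_node(gene("A"))
        with pytest.raises(ValidationError, match="duplicate id 'A'"):
            p.add_node(gene("A"))

    def test_group_node_requires_existing_members(self):
        p = Pathway("p").add_node(gene("A"))
        p.add_node(PathwayNode(id="G", kind="group", members=["A"]))
        assert p.nodes["G"].members == ["A"]
        with pytest.raises(ValidationError, match="unknown member"):
            p.add_node(PathwayNode(id="H", kind="group", members=["Z"]))

    def test_group_invariant_members_iff_group(self):
        with pytest.raises(ValidationError):
            PathwayNode(id="G", kind="group", members=[])
        with pytest.raises(ValidationError):
            PathwayNode(id="A", kind="gene", members=["B"])

    def test_remove_node_cascades_incident_edges(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1}, [("A", "B"), ("B", "C")])
        p.remove_node("B")
        assert set(p.nodes) == {"A", "C"}
        assert p.edges == []

    def test_remove_unknown_node_rejected(self):
        with pytest.raises(ValidationError, match="unknown node id 'Z'"):
            Pathway("p").remove_node("Z")

    def test_remove_node_purges_group_membership(self):
        p = Pathway("p").add_node(gene("A")).add_node(gene("B"))
        p.add_node(PathwayNode(id="G", kind="group", members=["A", "B"]))
        p.remove_node("A")
        assert p.nodes["G"].members == ["B"]


class TestEdgeEdits:
    def test_add_edge(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [])
        p.add_edge(PathwayEdge(source="A", target="B"))
        assert len(p.edges) == 1
        assert p.edges[0].provenance == "curated"

    def test_add_edge_unknown_target_rejected(self):
        p = build_pathway("p", {"A": 1}, [])
        with pytest.raises(ValidationError, match="unknown target 'Z'"):
            p.add_edge(PathwayEdge(source="A", target="Z"))

    def test_duplicate_source_target_subtype_rejected(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [("A", "B")])
        with pytest.raises(ValidationError, match="duplicate edge"):
            p.add_edge(PathwayEdge(source="A", target="B", subtype="activation"))
        # a different subtype between the same pair is allowed
        p.add_edge(PathwayEdge(source="A", target="B", subtype="phosphorylation"))
        assert len(p.edges) == 2

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError, match="weight"):
            PathwayEdge(source="A", target="B", weight=0.0)

    def test_set_edge_attributes_logs_old_and_new(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [("A", "B")])
        p.set_edge_attributes("A", "B", impact=-1)
        assert p.edges[0].impact == -1
        entry = p.curation_log[-1]
        assert entry.operation == "set_edge_attributes"
        assert entry.details["old"]["impact"] == 1
        assert entry.details["new"]["impact"] == -1

    def test_one_to_many_convenience(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1}, [])
        p.add_edges_from("A", ["B", "C"], impact=1)
        assert {(e.source, e.target) for e in p.edges} == {("A", "B"), ("A", "C")}


class TestDetectors:
    def test_disconnected_nodes_definition(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1, "D": 1},
                          [("A", "B"), ("B", "C")])
        assert p.detect_disconnected_nodes() == ["D"]

    def test_triangle_has_no_disconnected_nodes(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1},
                          [("A", "B"), ("B", "C"), ("C", "A")])
        assert p.detect_disconnected_nodes() == []

    @pytest.mark.parametrize("seed", range(10))
    def test_disconnected_matches_degree_scan(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"v{i}" for i in range(12)]
        arcs = {
            (ids[i], ids[j])
            for i in range(12) for j in range(12)
            if i != j and rng.random() < 0.12
        }
        p = build_pathway("p", {v: 1.0 for v in ids}, list(arcs))
        expected = sorted(
            v for v in ids
            if all(v not in (s, t) for s, t in arcs)
        )
        assert p.detect_disconnected_nodes() == expected

    def test_duplicates_same_gene(self):
        p = Pathway("p")
        p.nodes["e1"] = PathwayNode(id="e1", kind="gene", gene_ids=["7157"])
        p.nodes["e2"] = PathwayNode(id="e2", kind="gene", gene_ids=["7157"])
        p.nodes["e3"] = PathwayNode(id="e3", kind="gene", gene_ids=["7158"])
        assert p.detect_duplicates() == [["e1", "e2"]]

    def test_duplicates_all_unique(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [])
        assert p.detect_duplicates() == []

    def test_duplicates_respect_kind(self):
        p = Pathway("p")
        p.nodes["c1"] = PathwayNode(id="c1", kind="compound", gene_ids=["C00165"])
        p.nodes["g1"] = PathwayNode(id="g1", kind="gene", gene_ids=["C00165"])
        assert p.detect_duplicates() == []

    def test_cycle_detection_two_cycle_and_dag(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1},
                          [("A", "B"), ("B", "A"), ("A", "C")])
        assert p.detect_cycles() == [["A", "B"]]
        dag = build_pathway("p", {"A": 1, "B": 1}, [("A", "B")])
        assert dag.detect_cycles() == []

    def test_self_loop_reported_as_singleton(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [("A", "A"), ("A", "B")])
        assert p.detect_cycles() == [["A"]]

    @pytest.mark.parametrize("seed", range(15))
    def test_cycles_match_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ids = [f"v{i}" for i in range(10)]
        arcs = {
            (ids[i], ids[j])
            for i in range(10) for j in range(10)
            if rng.random() < 0.15
        }
        p = build_pathway("p", {v: 1.0 for v in ids}, list(arcs))
        reach = reachability_closure(ids, arcs)
        comps = {
            frozenset({u for u in ids if u in reach[v] and v in reach[u]} | {v})
            for v in ids
        }
        expected = sorted(
            sorted(c)
            for c in comps
            if len(c) > 1 or (min(c), min(c)) in arcs
        )
        assert p.detect_cycles() == expected

    def test_detectors_are_pure(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1},
                          [("A", "B"), ("B", "A")])
        before = (p.copy().nodes, [e for e in p.copy().edges])
        p.detect_cycles()
        p.detect_duplicates()
        p.detect_disconnected_nodes()
        assert p.nodes == before[0] and p.edges == before[1]


class TestCurationLog:
    def test_every_mutation_appends_exactly_one_entry(self):
        p = build_pathway("p", {"A": 1, "B": 1}, [])
        n0 = len(p.curation_log)
        p.add_edge(PathwayEdge(source="A", target="B"))
        p.set_edge_attributes("A", "B", weight=2.0)
        p.remove_edge("A", "B")
        p.remove_node("B")
        assert len(p.curation_log) == n0 + 4
        stamps = [e.timestamp for e in p.curation_log]
        assert stamps == sorted(stamps)

    def test_log_replay_reproduces_edit_sequence(self):
        rng = np.random.default_rng(7)
        base = build_pathway("p", {f"v{i}": 1.0 for i in range(6)},
                             [("v0", "v1"), ("v1", "v2")])
        edited = base.copy()
        existing = list(edited.nodes)
        for step in range(30):
            op = rng.integers(4)
            try:
                if op == 0:
                    nid = f"x{step}"
                    edited.add_node(gene(nid))
                    existing.append(nid)
                elif op == 1 and len(existing) > 2:
                    s, t = rng.choice(existing, size=2, replace=False)
                    edited.add_edge(PathwayEdge(source=str(s), target=str(t)))
                elif op == 2 and edited.edges:
                    e = edited.edges[int(rng.integers(len(edited.edges)))]
                    edited.set_edge_attributes(
                        e.source, e.target, e.subtype,
                        weight=float(rng.uniform(0.5, 2.0)),
                    )
                elif op == 3 and len(existing) > 4:
                    victim = str(rng.choice(existing))
                    edited.remove_node(victim)
                    existing.remove(victim)
            except ValidationError:
                continue  # duplicate edge etc. -- rejected edits log nothing
        new_entries = edited.curation_log[len(base.curation_log):]
        replayed = replay_log(base, new_entries)
        assert replayed.nodes == edited.nodes
        assert replayed.edges == edited.edges

    def test_replay_leaves_no_dangling_edges(self):
        p = build_pathway("p", {"A": 1, "B": 1, "C": 1},
                          [("A", "B"), ("B", "C"), ("A", "C")])
        p.remove_node("B")
        for e in p.edges:
            assert e.source in p.nodes and e.target in p.nodes
        p.validate()
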