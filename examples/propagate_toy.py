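"""Propagate fold changes through a hand-built five-node pathway.

A ligand (LIG) activates two branches: a kinase cascade (KIN -> TF) and an
inhibitory arm (INH -| TF).  We assign measured fold changes to the genes,
map them onto the nodes and propagate from the input to the sink.
"""

from psflow import Pathway, PathwayEdge, PathwayNode, map_to_nodes, propagate, sink_summary

pathway = Pathway("toy", name="toy receptor cascade")
for nid, gene in [("LIG", "lig1"), ("REC", "rec1"), ("KIN", "kin1"),
                  ("INH", "inh1"), ("TF", "tf1")]:
    pathway.nodes[nid] = PathwayNode(id=nid, label=nid, gene_ids=[gene])
for src, tgt, impact in [("LIG", "REC", 1), ("REC", "KIN", 1),
                         ("REC", "INH", 1), ("KIN", "TF", 1),
                         ("INH", "TF", -1)]:
    pathway.edges.append(PathwayEdge(
        source=src, target=tgt, impact=impact,
        subtype="activation" if impact == 1 else "inhibition",
    ))

# linear fold changes, e.g. tumour vs control: the ligand doubles, the
# inhibitor is halved
fold_changes = {"lig1": 2.0, "rec1": 1.2, "kin1": 1.0, "inh1": 0.5, "tf1": 1.0}

result = propagate(map_to_nodes(pathway, fold_changes))
print("node signals along the evaluation order:")
for nid in result.order:
    print(f"  {nid:4s} FC={result.fold_changes[nid]:<5.2f} S={result.signals[nid]:.4f}")
print()
print(sink_summary(result).to_string(index=False))
print()
print("TF integrates an activating and an inhibitory parent; its signal")
print("above 1 means the branch outcome is net activated in the case group.")
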