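"""Network-topology quality metrics for raw vs curated pathways.

Curation mostly adds edges (bridges, group links, recovered interactions),
so its effect shows up as more connected ordered pairs, larger diameter,
higher betweenness and fewer disconnected nodes.  :func:`topology_report`
computes that metric set on the directed graph; :func:`compare_reports`
tabulates before/after deltas.

Conventions (the directed case leaves genuine choices open):

* distances are unweighted edge counts,
* closeness and eccentricity use *outgoing* distances; nodes that reach
  nothing are excluded from the respective medians,
* medians use the midpoint convention, so fractional values are possible,
* the diameter of a graph with no finite path between distinct nodes is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Pathway


@dataclass(frozen=True)
class TopologyReport:
    shortest_path_pairs: int
    betweenness_median: float
    closeness_median: float
    eccentricity_median: float
    diameter: int
    disconnected_count: int
    sink_count: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {f.name: getattr(self, f.name) for f in fields(self)}, name="value"
        )


def topology_report(pathway: Pathway) -> TopologyReport:
    """Compute the topology metric set for one pathway.

    ``shortest_path_pairs`` counts ordered pairs (u, v), u != v, joined by
    a finite directed path — the quantity that grows as curation restores
    connectivity.  Betweenness is raw (unnormalized) directed betweenness.
    """
    if not pathway.nodes:
        raise ValidationError("topology_report: empty pathway")
    g = pathway.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(g))

    pairs = 0
    ecc: list[int] = []
    clo: list[float] = []
    diameter = 0
    for u in g.nodes:
        reach = {v: d for v, d in dist[u].items() if v != u}
        pairs += len(reach)
        if reach:
            far = max(reach.values())
            ecc.append(far)
            clo.append(len(reach) / sum(reach.values()))
            diameter = max(diameter, far)

    betw = nx.betweenness_centrality(g, normalized=False)
    return TopologyReport(
        shortest_path_pairs=pairs,
        betweenness_median=float(np.median(list(betw.values()))),
        closeness_median=float(np.median(clo)) if clo else 0.0,
        eccentricity_median=float(np.median(ecc)) if ecc else 0.0,
        diameter=diameter,
        disconnected_count=len(pathway.detect_disconnected_nodes()),
        sink_count=len(pathway.sinks()),
    )


def compare_reports(before: TopologyReport, after: TopologyReport) -> pd.DataFrame:
    """Per-metric before/after/delta table (delta = after - before)."""
    b, a = before.to_series(), after.to_series()
    return pd.DataFrame(
        {"metric": b.index, "before": b.values, "after": a.values,
         "delta": a.values - b.values}
    )


def report_to_tsv(report: TopologyReport, path) -> None:
    report.to_series().rename_axis("metric").reset_index().to_csv(
        path, sep="\t", index=False
    )


def report_from_tsv(path) -> TopologyReport:
    df = pd.read_csv(path, sep="\t").set_index("metric")["value"]
    kwargs = {f.name: f.type for f in fields(TopologyReport)}
    return TopologyReport(
        **{
            name: (int(df[name]) if kwargs[name] == "int" else float(df[name]))
            for name in kwargs
        }
    )
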