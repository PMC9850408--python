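"""Colocalization networks over one or more bait ions.

Each bait contributes a star of edges to the features that colocalize
with it above a PCC floor; features shared between baits appear once with
one edge per bait. Export to GraphML or a CSV edge list.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .coloc import ColocalizationResult, ThresholdBands

__all__ = ["build_network", "export_network", "read_network"]


def _band_label(p: float, bands: ThresholdBands) -> str:
    if p >= bands.high:
        return "high"
    if p >= bands.moderate_low:
        return "moderate"
    return "other"


def _node_name(mz: float) -> str:
    return f"{mz:.4f}"


def build_network(
    results: list[ColocalizationResult] | ColocalizationResult,
    floor: float = 0.6,
    bands: ThresholdBands | None = None,
) -> nx.Graph:
    """Assemble a bait→feature colocalization graph.

    One node per bait and per feature with PCC ≥ ``floor``; each edge
    carries ``pcc`` and a ``band`` label. Self-edges (the bait's own
    feature) are dropped. Feature↔feature correlations are not computed:
    the topology is a star per bait, so cost stays linear in features.
    """
    if isinstance(results, ColocalizationResult):
        results = [results]
    if not results:
        raise ValueError("need at least one colocalization result")
    bands = bands or ThresholdBands(high=0.9, moderate_low=min(0.6, floor))

    g = nx.Graph()
    for res in results:
        bait_node = _node_name(res.bait.mz)
        g.add_node(bait_node, kind="bait", mz=float(res.bait.mz), label=res.bait.label)
        kept = res.entries[res.entries["pcc"] >= floor]
        for row in kept.itertuples(index=False):
            feat_node = _node_name(row.feature_mz)
            if feat_node == bait_node:
                continue  # no self-edges
            if feat_node not in g:
                g.add_node(feat_node, kind="feature", mz=float(row.feature_mz), label="")
            g.add_edge(bait_node, feat_node, pcc=float(row.pcc),
                       band=_band_label(row.pcc, bands), bait=bait_node)
    g.graph["floor"] = floor
    return g


def export_network(net: nx.Graph, fmt: str, path) -> None:
    """Write the network as ``"graphml"`` or ``"edgelist_csv"``."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(net, str(path))
    elif fmt == "edgelist_csv":
        rows = [
            {"bait": d.get("bait", u), "feature": v if d.get("bait", u) == u else u,
             "pcc": d["pcc"], "band": d["band"]}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["bait", "feature", "pcc", "band"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use graphml or edgelist_csv")


def read_network(fmt: str, path) -> nx.Graph:
    """Re-import a network written by :func:`export_network`."""
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "edgelist_csv":
        df = pd.read_csv(path)
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.bait), str(row.feature), pcc=row.pcc, band=row.band)
        return g
    raise ValueError(f"unknown network format {fmt!r}")
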