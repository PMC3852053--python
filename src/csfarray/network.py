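"""Direct-interaction network construction and nodal-point ranking.

Given a curated gene-gene interaction database (an undirected edge list)
and a seed list of regulated genes, the direct-interaction network is the
subgraph of the database induced on the seeds, with each node annotated
by its regulation sign. "Nodal points" are the hubs of that subgraph,
operationalized as its highest-degree nodes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx


def load_interaction_db(path: str | Path) -> nx.Graph:
    """Read an interaction database from a SIF or 2/3-column TSV edge list.

    SIF rows are ``source<tab>mechanism<tab>target``; plain edge lists are
    ``source<tab>target[<tab>mechanism]``. Self-loops are ignored and
    duplicate edges collapse. The optional mechanism is kept as an edge
    attribute but plays no role in ranking.
    """
    g = nx.Graph()
    suffix = Path(path).suffix.lower()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0] or fields[0].startswith("#"):
                continue
            if suffix == ".sif" and len(fields) >= 3:
                u, mech, targets = fields[0], fields[1], fields[2:]
            else:
                u, targets = fields[0], fields[1:2]
                mech = fields[2] if len(fields) > 2 else None
            for v in targets:
                if v and v != u:
                    g.add_edge(u, v, **({"mechanism": mech} if mech else {}))
    return g


def build_direct_network(
    seeds: Mapping[str, float] | Iterable[tuple[str, float]],
    db: nx.Graph,
    drop_isolated: bool = False,
) -> nx.Graph:
    """Induce the interaction subgraph on a seed gene list.

    Parameters
    ----------
    seeds
        Mapping (or pairs) gene id -> signed fold change.
    db
        Interaction database graph.
    drop_isolated
        Drop seeds without any within-seed interaction from the node set.

    Returns
    -------
    networkx.Graph whose nodes carry a ``signed_fold`` attribute. Seeds
    absent from the database altogether are recorded in
    ``graph["unmapped"]`` (mirroring that only part of a regulated gene
    pool is typically annotated in curated databases).
    """
    pairs = list(seeds.items()) if isinstance(seeds, Mapping) else list(seeds)
    seed_map = dict(pairs)
    if len(seed_map) != len(pairs):
        raise ValueError("seed ids must be unique")
    net = nx.Graph()
    unmapped = sorted(s for s in seed_map if s not in db)
    for s, fold in seed_map.items():
        if s in db:
            net.add_node(s, signed_fold=fold)
    net.add_edges_from(
        (u, v, db.edges[u, v])
        for u, v in db.edges(net.nodes)
        if u in net.nodes and v in net.nodes
    )
    if drop_isolated:
        net.remove_nodes_from([n for n, d in dict(net.degree()).items() if d == 0])
    net.graph["unmapped"] = unmapped
    return net


def rank_nodal_points(net: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-``k`` hubs by degree (descending), ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.degree(), key=lambda nd: (-nd[1], str(nd[0])))
    return [(n, int(d)) for n, d in ranked[:k]]


def write_sif(net: nx.Graph, path: str | Path, default_mechanism: str = "interacts") -> None:
    """Write the network as SIF (isolated nodes as bare rows)."""
    with open(path, "w") as fh:
        for u, v, attrs in net.edges(data=True):
            fh.write(f"{u}\t{attrs.get('mechanism', default_mechanism)}\t{v}\n")
        for n in nx.isolates(net):
            fh.write(f"{n}\n")


def degree_report(net: nx.Graph, k: int | None = None) -> dict:
    """JSON-ready summary: node count, edge count, unmapped seeds, top hubs."""
    k = k if k is not None else net.number_of_nodes()
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "unmapped_seeds": list(net.graph.get("unmapped", [])),
        "nodal_points": [
            {"gene": n, "degree": d} for n, d in rank_nodal_points(net, max(k, 1))
        ]
        if net.number_of_nodes()
        else [],
    }
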