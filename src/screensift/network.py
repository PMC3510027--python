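"""Hit-network construction over a user-supplied interactome.

Two network styles mirror common screen follow-up analyses:

* **direct network** — the subgraph induced on the hit (seed) genes,
  keeping only seeds with at least one edge to another seed;
* **shortest-path network** — seeds plus intervening *connector* nodes:
  for every seed pair whose shortest interactome path needs at most
  ``max_intervening`` non-seed interior nodes, one canonical shortest
  path is included (deterministic lexicographic tie-break).

Edges carry a relation kind, ``direct`` (physical contact) or
``indirect`` (functional), and traversal can be restricted to direct
relations only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

RELATION_KINDS = ("direct", "indirect")
# common SIF relation tokens mapped onto the two kinds
_RELATION_ALIASES = {
    "direct": "direct",
    "pp": "direct",
    "indirect": "indirect",
}


class NetworkError(ValueError):
    """Raised on malformed interactome input or invalid seeds."""


def read_interactome(path) -> nx.Graph:
    """Read a SIF ("A relation B") or 3-column TSV edge list.

    Edges are undirected and deduplicated; self-loop rows are dropped
    with a warning; an unknown relation token is an error.  Relation
    kinds are kept as the ``relation`` edge attribute; if a duplicated
    edge appears with both kinds, ``direct`` wins.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise NetworkError(
                    f"line {lineno}: expected 'node relation node', got {len(parts)} fields"
                )
            a, rel, b = parts
            kind = _RELATION_ALIASES.get(rel.lower())
            if kind is None:
                raise NetworkError(f"line {lineno}: unknown relation kind {rel!r}")
            if a == b:
                logger.warning("line %d: self-loop %s dropped", lineno, a)
                continue
            if g.has_edge(a, b) and g.edges[a, b]["relation"] == "direct":
                continue
            g.add_edge(a, b, relation=kind)
    return g


def _restrict(g: nx.Graph, direct_only: bool) -> nx.Graph:
    if not direct_only:
        return g
    keep = [(u, v) for u, v, d in g.edges(data=True) if d["relation"] == "direct"]
    return g.edge_subgraph(keep).copy()


@dataclass
class HitNetwork:
    """A constructed hit network: graph plus per-node role flags.

    Roles are ``seed`` (hit gene), ``connector`` (intervening node on a
    kept shortest path) or ``focus`` (a manually added gene of interest).
    """

    graph: nx.Graph
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def members(self) -> set[str]:
        return set(self.graph.nodes)

    def degree_of(self, node: str) -> int:
        return int(self.graph.degree(node))


def direct_subnetwork(g: nx.Graph, seeds, direct_only: bool = False) -> HitNetwork:
    """Induced subgraph on the seeds, with isolated seeds removed.

    A seed enters the network only if it connects to another seed with
    no intervening nodes.  An empty result is allowed.
    """
    seeds = set(seeds)
    if not seeds:
        raise NetworkError("empty seed set")
    gg = _restrict(g, direct_only)
    sub = gg.subgraph(seeds & set(gg.nodes)).copy()
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return HitNetwork(sub, {n: "seed" for n in sub.nodes})


def add_focus_node(net: HitNetwork, g: nx.Graph, focus_id: str) -> HitNetwork:
    """Add a focus gene and all its interactome edges to current members.

    The focus is added even when no edge to a member exists (isolated,
    flagged), matching the practice of manually placing a protein of
    interest in a constructed network to inspect its connections.
    """
    if focus_id not in g:
        raise NetworkError(f"focus node {focus_id!r} absent from interactome")
    out = HitNetwork(net.graph.copy(), dict(net.roles))
    out.graph.add_node(focus_id)
    out.roles[focus_id] = "focus"
    for nbr in g.neighbors(focus_id):
        if nbr in net.members and nbr != focus_id:
            out.graph.add_edge(focus_id, nbr, **g.edges[focus_id, nbr])
    return out


def _canonical_shortest_path(
    g: nx.Graph, source: str, target: str, seeds: set[str], max_intervening: int
) -> list[str] | None:
    """Lexicographically smallest shortest path whose non-seed interior
    count is within ``max_intervening``; None if no such path exists."""
    try:
        paths = nx.all_shortest_paths(g, source, target)
        best = None
        for p in paths:
            interior = p[1:-1]
            if sum(1 for n in interior if n not in seeds) > max_intervening:
                continue
            key = tuple(interior)
            if best is None or key < tuple(best[1:-1]):
                best = p
        return best
    except nx.NetworkXNoPath:
        return None


def shortest_path_network(
    g: nx.Graph, seeds, max_intervening: int = 1, direct_only: bool = False
) -> HitNetwork:
    """Connect seeds through at most ``max_intervening`` non-seed nodes.

    For every unordered seed pair, the interactome's shortest paths are
    examined; if one uses at most ``max_intervening`` non-seed interior
    nodes, the lexicographically smallest such path (by interior node
    sequence, source < target) is added.  Interior nodes are flagged
    ``connector``.  Seeds in the interactome that end up unconnected
    remain in the network as isolated seeds.
    """
    if max_intervening < 0:
        raise NetworkError("max_intervening must be >= 0")
    seeds = set(seeds)
    if not seeds:
        raise NetworkError("empty seed set")
    gg = _restrict(g, direct_only)
    present = sorted(seeds & set(gg.nodes))
    out = nx.Graph()
    out.add_nodes_from(present)
    for a, b in itertools.combinations(present, 2):
        path = _canonical_shortest_path(gg, a, b, seeds, max_intervening)
        if path is None:
            continue
        for u, v in zip(path, path[1:]):
            out.add_edge(u, v, **gg.edges[u, v])
    roles = {n: ("seed" if n in seeds else "connector") for n in out.nodes}
    return HitNetwork(out, roles)


def degree_report(net: HitNetwork) -> pd.DataFrame:
    """Per-node degree table, sorted descending by degree then node id."""
    rows = [
        {"node": n, "flag": net.roles.get(n, "seed"), "degree": int(net.graph.degree(n))}
        for n in net.graph.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "flag", "degree"])
    return df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(
        drop=True
    )


def write_graphml(net: HitNetwork, path) -> None:
    g = net.graph.copy()
    nx.set_node_attributes(g, net.roles, "flag")
    nx.write_graphml(g, path)


def write_dot(net: HitNetwork, path) -> None:
    """Minimal DOT export: solid edges for direct relations, dotted for
    indirect; connectors drawn as ellipses, seeds as boxes."""
    shape = {"seed": "box", "connector": "ellipse", "focus": "diamond"}
    lines = ["graph hits {"]
    for n in sorted(net.graph.nodes):
        role = net.roles.get(n, "seed")
        lines.append(f'  "{n}" [shape={shape.get(role, "box")}, comment="{role}"];')
    for u, v, d in sorted(net.graph.edges(data=True)):
        style = "solid" if d.get("relation", "direct") == "direct" else "dotted"
        lines.append(f'  "{u}" -- "{v}" [style={style}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
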