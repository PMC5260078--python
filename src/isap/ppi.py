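"""Shortest-path PPI subnetwork among aging markers, with a permutation test.

From a STRING-flavour weighted edge list (confidence scores 0-1000, edges
kept when score > 700 by default) the module extracts, for every pair of
marker genes in the same connected component, one shortest path; the union
of those paths is the marker subnetwork.  A node's *betweenness* here is the
count of marker-pair paths passing strictly through it (endpoints excluded)
— a path-count, not the normalized centrality of graph theory.

Significance of a focal node's betweenness is assessed by re-running the
whole construction on random node sets of the same size: p is the fraction
of permutations in which the focal node's betweenness is at least the
observed one (weak inequality, the conservative reading).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_SCORE_CUTOFF = 700


def load_string_edges(path, score_cutoff: int = DEFAULT_SCORE_CUTOFF) -> nx.Graph:
    """Build the background graph from a STRING-flavour edge list.

    Rows are whitespace/tab separated: node, node, integer score.  A header
    row is tolerated.  Edges are kept iff score > cutoff (strict); the graph
    is undirected with self-loops and duplicates collapsed (max score kept).
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'node node score'")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = int(float(raw))
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if a == b or score <= score_cutoff:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    if graph.number_of_edges() == 0:
        raise ValueError(f"no edges remain after applying score cutoff {score_cutoff}")
    log.info("PPI graph: %d nodes, %d edges (score > %d)",
             graph.number_of_nodes(), graph.number_of_edges(), score_cutoff)
    return graph


def write_string_edges(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for a, b, d in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['score']}\n")


@dataclass
class ShortestPathSubnetwork:
    markers: list[str]  # markers found in the graph
    subgraph: nx.Graph  # union of computed shortest paths
    betweenness: dict[str, int]  # node -> marker-pair path count (interior only)
    paths: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def ranked(self) -> pd.DataFrame:
        rows = sorted(self.betweenness.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["gene", "betweenness"])


def _bfs_dist(adj: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def _lex_shortest_path(adj: dict[str, list[str]], dist_to_target: dict[str, int], source: str, target: str) -> list[str]:
    # Greedy over sorted neighbours => lexicographically smallest node sequence
    # among all shortest paths (any feasible next hop extends to a shortest path).
    path = [source]
    v = source
    while v != target:
        d = dist_to_target[v]
        v = min(u for u in adj[v] if dist_to_target.get(u, -1) == d - 1)
        path.append(v)
    return path


def marker_shortest_paths(graph: nx.Graph, markers, tie_mode: str = "single") -> ShortestPathSubnetwork:
    """Shortest paths (hop metric) between all connected marker pairs.

    ``tie_mode='single'`` keeps one deterministic path per pair (the
    lexicographically smallest node sequence); ``'all'`` counts every tied
    shortest path.  Markers absent from the graph are logged and excluded.
    """
    markers = list(dict.fromkeys(markers))
    present = sorted(m for m in markers if m in graph)
    absent = len(markers) - len(present)
    if absent:
        log.info("%d of %d markers not in the PPI graph; excluded", absent, len(markers))
    adj = {v: sorted(graph.neighbors(v)) for v in graph.nodes}
    dist = {m: _bfs_dist(adj, m) for m in present}

    betweenness: dict[str, int] = {}
    sub = nx.Graph()
    paths: dict[tuple[str, str], list[str]] = {}
    n_connected = 0
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            if b not in dist[a]:
                continue
            n_connected += 1
            if tie_mode == "single":
                pair_paths = [_lex_shortest_path(adj, dist[b], a, b)]
            elif tie_mode == "all":
                pair_paths = [list(p) for p in nx.all_shortest_paths(graph, a, b)]
            else:
                raise ValueError(f"unknown tie_mode {tie_mode!r}")
            paths[(a, b)] = pair_paths[0]
            for p in pair_paths:
                nx.add_path(sub, p)
                for v in p[1:-1]:
                    betweenness[v] = betweenness.get(v, 0) + 1
    if n_connected == 0:
        log.warning("no marker pair is connected; subnetwork is empty")
    for v in sub.nodes:
        betweenness.setdefault(v, 0)
    for a, b in sub.edges:
        sub[a][b]["score"] = graph[a][b].get("score", 0)
    return ShortestPathSubnetwork(markers=present, subgraph=sub, betweenness=betweenness, paths=paths)


def betweenness_permutation_test(
    graph: nx.Graph,
    markers,
    focal_nodes,
    n_perm: int = 1000,
    seed: int = 0,
    tie_mode: str = "single",
    tie_break: str = "none",
    observed: dict[str, int] | None = None,
) -> dict[str, float]:
    """Permutation p-values for focal nodes' betweenness.

    Each permutation draws a uniform node set of the marker count and
    recomputes the subnetwork.  ``tie_break='none'`` (default) reports the
    plain proportion p = #(perm >= obs)/n_perm, which is discrete and
    conservative under ties (a focal betweenness of 0 gives p = 1).
    ``tie_break='randomized'`` returns the exchangeable randomized-rank
    p-value, exactly uniform under the null; useful for calibration checks.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    focal = list(focal_nodes)
    missing = [f for f in focal if f not in graph]
    if missing:
        raise KeyError(f"focal nodes not in graph: {missing}")
    if observed is None:
        observed = marker_shortest_paths(graph, markers, tie_mode=tie_mode).betweenness
    obs = {f: observed.get(f, 0) for f in focal}

    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    size = len([m for m in dict.fromkeys(markers) if m in graph])
    ge = {f: 0 for f in focal}
    gt = {f: 0 for f in focal}
    for _ in range(n_perm):
        random_set = rng.choice(nodes, size=size, replace=False)
        b = marker_shortest_paths(graph, list(random_set), tie_mode=tie_mode).betweenness
        for f in focal:
            val = b.get(f, 0)
            if val >= obs[f]:
                ge[f] += 1
            if val > obs[f]:
                gt[f] += 1
    if tie_break == "none":
        return {f: ge[f] / n_perm for f in focal}
    if tie_break == "randomized":
        return {
            f: (gt[f] + rng.uniform() * (ge[f] - gt[f] + 1)) / (n_perm + 1)
            for f in focal
        }
    raise ValueError(f"unknown tie_break {tie_break!r}")


def format_permutation_p(p: float, n_perm: int) -> str:
    """Report at the test's resolution; p = 0 becomes '< 1/n_perm'."""
    return f"<{1.0 / n_perm:g}" if p == 0 else f"{p:.4g}"


def betweenness_table(subnet: ShortestPathSubnetwork, pvalues: dict[str, float], n_perm: int) -> pd.DataFrame:
    """Ranked betweenness table with permutation p-values and significance stars."""
    table = subnet.ranked()
    table["p_value"] = [pvalues.get(g, float("nan")) for g in table["gene"]]
    table["p_label"] = [
        format_permutation_p(p, n_perm) if pd.notna(p) else ""
        for p in table["p_value"]
    ]
    table["significant"] = table["p_value"] < 0.05
    return table
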