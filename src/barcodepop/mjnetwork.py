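"""Median-joining haplotype networks.

Implements the median-joining construction of Bandelt, Forster & Roehl: a
minimum spanning network (the union of all minimum spanning trees within a
tolerance epsilon) is iteratively enriched with quasi-median ("median
vector") sequences of connected triplets whenever adding one reduces the
total (Steiner) cost of the network, measured as the weight of a minimum
spanning tree over the current node set.  Obsolete median vectors are pruned
at the end.  All tie-breaks are lexicographic on node sequence/id, so the
output is deterministic under a fixed input (the original program is
order-dependent).

Character weights are uniform and epsilon defaults to 0, matching the
"default settings" of the commonly used desktop implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sequence_io import HaplotypeSet

MISSING = frozenset("N-")


def hamming(a: str, b: str) -> int:
    """Number of differing sites; sites with N/- in either are skipped."""
    return sum(
        1 for x, y in zip(a, b) if x != y and x not in MISSING and y not in MISSING
    )


def hamming_matrix(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = hamming(seqs[i], seqs[j])
    return out


def _mst_cost(dm: np.ndarray) -> int:
    """Prim's MST total weight (zero-weight links are legitimate edges)."""
    n = dm.shape[0]
    if n < 2:
        return 0
    best = dm[0].astype(float).copy()
    best[0] = np.inf
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    total = 0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, dm[j].astype(float))
        best[in_tree] = np.inf
    return total


def _connection_levels(dm: np.ndarray) -> np.ndarray:
    """Single-linkage merge heights c(u,v) for every pair (u, v)."""
    n = dm.shape[0]
    levels = np.zeros((n, n), dtype=np.int64)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    comp_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    iu = np.triu_indices(n, k=1)
    order = np.argsort(dm[iu], kind="stable")
    pairs = list(zip(iu[0][order], iu[1][order]))
    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri == rj:
            continue
        d = int(dm[i, j])
        for a in comp_members[ri]:
            for b in comp_members[rj]:
                levels[a, b] = levels[b, a] = d
        comp_members[ri].extend(comp_members[rj])
        parent[rj] = ri
        del comp_members[rj]
    return levels


def msn_edges(dm: np.ndarray, eps: int = 0) -> list[tuple[int, int, int]]:
    """Minimum spanning network: edges (i, j, d) with d <= c(i, j) + eps,
    where c is the single-linkage connection level of i and j."""
    n = dm.shape[0]
    levels = _connection_levels(dm)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dm[i, j])
            if d <= levels[i, j] + eps:
                edges.append((i, j, d))
    return edges


def _quasi_medians(u: str, v: str, w: str, cap: int = 27) -> list[str]:
    """Quasi-median sequences of a triplet: per-site majority consensus;
    sites where all three states differ branch into each of the three
    states.  Returns [] if the branching would exceed ``cap`` sequences."""
    base = []
    free: list[tuple[int, tuple[str, str, str]]] = []
    for i, (x, y, z) in enumerate(zip(u, v, w)):
        if x == y or x == z:
            base.append(x)
        elif y == z:
            base.append(y)
        else:
            base.append("?")
            free.append((i, (x, y, z)))
    if 3 ** len(free) > cap:
        return []
    out = []
    for combo in itertools.product(*[states for _, states in free]):
        s = base.copy()
        for (i, _), c in zip(free, combo):
            s[i] = c
        out.append("".join(s))
    return sorted(out)


@dataclass
class HaploNetwork:
    """A haplotype network: sampled nodes plus inferred median vectors."""

    graph: nx.Graph  # nodes carry sequence/kind/count/populations attrs

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"]

    @property
    def median_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "median-vector"
        ]

    def total_cost(self) -> int:
        seqs = [d["sequence"] for _, d in sorted(self.graph.nodes(data=True))]
        return _mst_cost(hamming_matrix(seqs))

    def write_gml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n,
                sequence=d["sequence"],
                kind=d["kind"],
                count=int(d["count"]),
                populations=";".join(
                    f"{k}:{v}" for k, v in sorted(d.get("populations", {}).items())
                ),
            )
        for a, b, d in self.graph.edges(data=True):
            g.add_edge(a, b, weight=int(d["weight"]))
        nx.write_gml(g, str(path))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "weight": int(d["weight"])}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            row = {"node_id": n, "kind": d["kind"], "count": int(d["count"])}
            for pop, c in sorted(d.get("populations", {}).items()):
                row[f"pop_{pop}"] = c
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def build_mj(
    haps: HaplotypeSet,
    eps: int = 0,
    populations: Mapping[str, str] | None = None,
    max_medians: int = 200,
) -> HaploNetwork:
    """Median-joining network of a haplotype set.

    ``populations`` optionally maps member sequence ids to population labels
    for per-node annotation.  ``max_medians`` bounds the number of inferred
    median vectors (a safety valve; the Steiner criterion normally converges
    long before).
    """
    seqs = [h.sequence for h in haps.haplotypes]
    sampled = {s: h for s, h in zip(seqs, haps.haplotypes)}
    nodes = sorted(seqs)
    known = set(nodes)

    while len(known) - len(seqs) < max_medians:
        dm = hamming_matrix(nodes)
        cost = _mst_cost(dm)
        edges = msn_edges(dm, eps)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        # connected triplets: a centre node with two linked neighbours
        candidates: set[str] = set()
        for u in range(len(nodes)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for m in _quasi_medians(nodes[u], nodes[v], nodes[w]):
                    if m not in known:
                        candidates.add(m)
        if not candidates:
            break
        best_seq = None
        best_cost = cost
        for m in sorted(candidates):
            d_new = np.array([hamming(m, s) for s in nodes])
            dm2 = np.zeros((len(nodes) + 1, len(nodes) + 1), dtype=np.int64)
            dm2[: len(nodes), : len(nodes)] = dm
            dm2[-1, :-1] = d_new
            dm2[:-1, -1] = d_new
            c2 = _mst_cost(dm2)
            if c2 < best_cost:
                best_cost = c2
                best_seq = m
        if best_seq is None:
            break
        nodes = sorted(nodes + [best_seq])
        known.add(best_seq)

    # prune median vectors whose removal leaves the Steiner cost unchanged
    changed = True
    while changed:
        changed = False
        cost = _mst_cost(hamming_matrix(nodes))
        for m in sorted(n for n in nodes if n not in sampled):
            rest = [s for s in nodes if s != m]
            if _mst_cost(hamming_matrix(rest)) <= cost:
                nodes = rest
                changed = True
                break

    # assemble final graph with MSN edges over the final node set
    dm = hamming_matrix(nodes)
    edges = msn_edges(dm, eps)
    g = nx.Graph()
    med_idx = 0
    node_ids = []
    for s in nodes:
        if s in sampled:
            h = sampled[s]
            pops: dict[str, int] = {}
            if populations:
                for mid in h.member_ids:
                    p = populations.get(mid, "")
                    pops[p] = pops.get(p, 0) + 1
            g.add_node(
                h.hap_id, sequence=s, kind="sampled", count=h.count, populations=pops
            )
            node_ids.append(h.hap_id)
        else:
            med_idx += 1
            nid = f"mv{med_idx}"
            g.add_node(nid, sequence=s, kind="median-vector", count=0, populations={})
            node_ids.append(nid)
    for i, j, d in edges:
        g.add_edge(node_ids[i], node_ids[j], weight=d)
    return HaploNetwork(graph=g)


def group_separation(
    net: HaploNetwork, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Minimum path weight between sampled nodes of different groups.

    ``labels`` maps sampled node ids (haplotype ids) to group labels.
    Disconnected group pairs get infinite separation (with a warning column).
    """
    groups: dict[str, list[str]] = {}
    for node in net.sampled_nodes:
        lab = labels.get(node)
        if lab is None:
            continue
        groups.setdefault(lab, []).append(node)
    names = sorted(groups)
    rows = []
    for ai, ga in enumerate(names):
        for gb in names[ai + 1 :]:
            best = float("inf")
            dist_from_a = nx.multi_source_dijkstra_path_length(
                net.graph, set(groups[ga]), weight="weight"
            )
            for tgt in groups[gb]:
                if tgt in dist_from_a:
                    best = min(best, dist_from_a[tgt])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "min_path_weight": best,
                    "connected": best != float("inf"),
                }
            )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "min_path_weight", "connected"]
    )
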