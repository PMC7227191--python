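"""Median-joining haplotype network construction and export.

The construction follows the classic median-joining scheme: starting from the
epsilon-relaxed minimum spanning network (MSN) over the observed haplotypes,
candidate median (consensus) vectors are generated from connected triplets,
the cheapest ones (within epsilon of the minimum connection cost) are added
as latent nodes, and the MSN is rebuilt until stable; latent nodes that end
up with degree < 3 cannot be Steiner points and are pruned. With epsilon = 0
the network restricted to observed haplotypes always contains a minimum
spanning tree under Hamming distance.

Nodes carry haplotype frequency and per-population composition; edges carry
the number of mutational steps and the differing 1-based site positions, the
data behind the usual pie-chart network figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable

__all__ = ["HaplotypeNetwork", "build_mjn", "export_network"]


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: sequence, frequency, is_median, populations
    epsilon: int

    @property
    def observed_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d["is_median"]]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diff_positions(a: str, b: str) -> list[int]:
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _msn_edges(seqs: dict[str, str], epsilon: int) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A candidate edge of weight w enters iff its endpoints are not already
    connected using only edges of weight < w - epsilon; all ties at a weight
    level are evaluated against the same connectivity state, so the result is
    the union of all minimum spanning trees when epsilon = 0.
    """
    names = list(seqs)
    if len(names) == 1:
        return []
    pairs = [
        (u, v, _hamming(seqs[u], seqs[v]))
        for i, u in enumerate(names)
        for v in names[i + 1 :]
    ]
    pairs.sort(key=lambda t: t[2])
    weights = sorted({w for _, _, w in pairs})
    g = nx.Graph()
    g.add_nodes_from(names)
    edges: list[tuple[str, str, int]] = []
    for w in weights:
        # connectivity from strictly cheaper (minus relaxation) edges only
        gw = nx.Graph()
        gw.add_nodes_from(names)
        gw.add_edges_from((u, v) for u, v, ew in edges if ew < w - epsilon)
        comp = {n: i for i, cc in enumerate(nx.connected_components(gw)) for n in cc}
        for u, v, ew in pairs:
            if ew == w and comp[u] != comp[v]:
                edges.append((u, v, ew))
    return edges


def _median(a: str, b: str, c: str) -> str:
    """Site-wise majority consensus of three sequences (ties resolved to the
    first sequence's state, which never creates a fourth allele)."""
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def build_mjn(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network of the haplotypes in ``table``."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    seqs: dict[str, str] = dict(zip(table.labels, table.sequences))
    n_medians = 0
    known = set(seqs.values())

    while True:
        edges = _msn_edges(seqs, epsilon)
        adj: dict[str, set[str]] = {v: set() for v in seqs}
        for u, v, _ in edges:
            adj[u].add(v)
            adj[v].add(u)
        # candidate triplets: a node with two neighbours (connected triples)
        candidates: dict[str, int] = {}
        for v, nbrs in adj.items():
            nb = sorted(nbrs)
            for i, u in enumerate(nb):
                for w in nb[i + 1 :]:
                    m = _median(seqs[v], seqs[u], seqs[w])
                    if m in known:
                        continue
                    cost = (
                        _hamming(m, seqs[u])
                        + _hamming(m, seqs[v])
                        + _hamming(m, seqs[w])
                    )
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        lam_min = min(candidates.values())
        added = False
        for m, cost in candidates.items():
            if cost <= lam_min + epsilon:
                n_medians += 1
                seqs[f"mv{n_medians}"] = m
                known.add(m)
                added = True
        if not added:
            break

    # prune latent vectors that cannot be Steiner points (degree < 3)
    while True:
        edges = _msn_edges(seqs, epsilon)
        deg: dict[str, int] = {v: 0 for v in seqs}
        for u, v, _ in edges:
            deg[u] += 1
            deg[v] += 1
        drop = [v for v in seqs if v.startswith("mv") and deg[v] < 3]
        if not drop:
            break
        for v in drop:
            known.discard(seqs[v])
            del seqs[v]

    g = nx.Graph()
    freq = dict(zip(table.labels, (int(c) for c in table.total_counts)))
    for v, s in seqs.items():
        is_median = v.startswith("mv")
        comp = (
            {}
            if is_median
            else {p: int(c) for p, c in table.counts.loc[v].items() if c > 0}
        )
        g.add_node(
            v,
            sequence=s,
            frequency=0 if is_median else freq[v],
            is_median=is_median,
            populations=comp,
        )
    for u, v, w in _msn_edges(seqs, epsilon):
        g.add_edge(u, v, steps=w, positions=_diff_positions(seqs[u], seqs[v]))
    return HaplotypeNetwork(g, epsilon)


def export_network(net: HaplotypeNetwork, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML, node+edge TSVs, or DOT.

    For ``fmt="tsv"`` two files are written: ``<path>.nodes.tsv`` and
    ``<path>.edges.tsv``; the returned path is the node table.
    """
    path = Path(path)
    g = net.graph
    if fmt == "graphml":
        out = nx.Graph()
        for v, d in g.nodes(data=True):
            out.add_node(
                v,
                sequence=d["sequence"],
                frequency=d["frequency"],
                is_median=d["is_median"],
                populations=";".join(f"{p}:{c}" for p, c in d["populations"].items()),
            )
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, steps=d["steps"],
                         positions=",".join(map(str, d["positions"])))
        nx.write_graphml(out, path)
        return path
    if fmt == "tsv":
        nodes = pd.DataFrame(
            [
                {
                    "node": v,
                    "sequence": d["sequence"],
                    "frequency": d["frequency"],
                    "is_median": d["is_median"],
                    **{f"count_{p}": c for p, c in d["populations"].items()},
                }
                for v, d in g.nodes(data=True)
            ]
        ).fillna(0)
        edges = pd.DataFrame(
            [
                {
                    "node_a": u,
                    "node_b": v,
                    "steps": d["steps"],
                    "positions": ",".join(map(str, d["positions"])),
                }
                for u, v, d in g.edges(data=True)
            ]
        )
        node_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        nodes.to_csv(node_path, sep="\t", index=False)
        edges.to_csv(edges_path, sep="\t", index=False)
        return node_path
    if fmt == "dot":
        lines = ["graph haplotypes {"]
        for v, d in g.nodes(data=True):
            shape = "point" if d["is_median"] else "circle"
            lines.append(f'  "{v}" [shape={shape}, label="{v} ({d["frequency"]})"];')
        for u, v, d in g.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [label="{d["steps"]}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unsupported format {fmt!r}")
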