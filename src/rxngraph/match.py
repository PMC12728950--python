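"""Subgraph matching, indexed substructure search and template clustering.

``find_embeddings`` is a VF2-style backtracking monomorphism enumerator
(noninduced by default) over simple undirected labeled graphs; it backs the
isomorphism check, the SING verifier and the DPO reactor.  ``SingIndex``
implements fingerprint-based candidate filtering: per-node labeled path
signatures up to a depth ``d`` shortlist host graphs and host nodes, and the
backtracking verifier confirms, so query results are identical to a naive
sweep.  ``cluster`` buckets graphs by their WL hash and runs exact
isomorphism linkage within buckets, which provably equals exhaustive
all-pairs clustering; ``batch_cluster`` partitions the input, clusters the
batches and merges representatives without changing the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import networkx as nx

from . import canon
from .canon import NodeLabel, EdgeLabel, _default_edge_label, _default_node_label
from .errors import ValidationError

Embedding = dict


# ---------------------------------------------------------------------------
# backtracking monomorphism search
# ---------------------------------------------------------------------------

def _pattern_order(pattern: nx.Graph) -> list:
    """Search order: within each component start at the highest-degree node
    and grow along adjacency so candidates stay constrained."""
    order: list = []
    seen: set = set()
    for comp in sorted(nx.connected_components(pattern), key=lambda c: sorted(map(repr, c))):
        comp = set(comp)
        start = max(sorted(comp, key=repr), key=lambda v: pattern.degree[v])
        frontier = [start]
        while frontier:
            v = frontier.pop(0)
            if v in seen:
                continue
            seen.add(v)
            order.append(v)
            frontier.extend(sorted((u for u in pattern[v] if u not in seen), key=repr))
        for v in sorted(comp - seen, key=repr):  # isolated nodes
            seen.add(v)
            order.append(v)
    return order


def find_embeddings(pattern: nx.Graph, host: nx.Graph, induced: bool = False,
                    node_label: NodeLabel = _default_node_label,
                    edge_label: EdgeLabel = _default_edge_label,
                    candidates: Mapping | None = None,
                    limit: int | None = None,
                    first_only: bool = False) -> list[Embedding]:
    """Enumerate injective label-preserving maps of ``pattern`` into ``host``.

    Noninduced by default: host may have extra edges between matched nodes;
    with ``induced=True`` pattern non-edges must map to host non-edges.
    ``candidates`` optionally restricts each pattern node to a host-node
    subset (used by the SING prefilter).  Results are returned in a
    deterministic order, sorted by the tuple of host images over the sorted
    pattern nodes.
    """
    if pattern.number_of_nodes() == 0:
        return [{}]
    if pattern.number_of_nodes() > host.number_of_nodes():
        return []
    plab = {v: node_label(pattern.nodes[v]) for v in pattern.nodes}
    hlab = {v: node_label(host.nodes[v]) for v in host.nodes}
    by_label: dict = {}
    for v in sorted(host.nodes, key=repr):
        by_label.setdefault(hlab[v], []).append(v)
    # fail fast when some pattern label is absent from the host
    for v in pattern.nodes:
        if plab[v] not in by_label:
            return []

    order = _pattern_order(pattern)
    pos = {v: i for i, v in enumerate(order)}
    # pattern neighbours already placed when a node is reached
    back = {v: [u for u in pattern[v] if pos[u] < pos[v]] for v in order}

    results: list[Embedding] = []
    mapping: dict = {}
    used: set = set()

    def feasible(pv, hv) -> bool:
        if hv in used or plab[pv] != hlab[hv]:
            return False
        if pattern.degree[pv] > host.degree[hv]:
            return False
        if candidates is not None and hv not in candidates.get(pv, ()):
            return False
        for pu in back[pv]:
            hu = mapping[pu]
            if not host.has_edge(hu, hv):
                return False
            if edge_label(pattern.edges[pu, pv]) != edge_label(host.edges[hu, hv]):
                return False
        if induced:
            for pu, hu in mapping.items():
                if not pattern.has_edge(pu, pv) and host.has_edge(hu, hv):
                    return False
        return True

    def extend(i: int) -> bool:
        if i == len(order):
            results.append(dict(mapping))
            if first_only or (limit is not None and len(results) >= limit):
                return True
            return False
        pv = order[i]
        if back[pv]:
            pool = sorted(host[mapping[back[pv][0]]], key=repr)
        else:
            pool = by_label[plab[pv]]
        for hv in pool:
            if feasible(pv, hv):
                mapping[pv] = hv
                used.add(hv)
                if extend(i + 1):
                    return True
                used.remove(hv)
                del mapping[pv]
        return False

    extend(0)
    keys = sorted(pattern.nodes, key=repr)
    results.sort(key=lambda m: tuple(repr(m[k]) for k in keys))
    return results


def is_isomorphic(a: nx.Graph, b: nx.Graph,
                  node_label: NodeLabel = _default_node_label,
                  edge_label: EdgeLabel = _default_edge_label) -> bool:
    """Exact label-preserving graph isomorphism."""
    if a.number_of_nodes() != b.number_of_nodes() or a.number_of_edges() != b.number_of_edges():
        return False
    la = sorted(repr(node_label(a.nodes[v])) for v in a.nodes)
    lb = sorted(repr(node_label(b.nodes[v])) for v in b.nodes)
    if la != lb:
        return False
    if sorted(dict(a.degree).values()) != sorted(dict(b.degree).values()):
        return False
    # an injective monomorphism between graphs of equal size and edge count
    # is a full isomorphism
    return bool(find_embeddings(a, b, induced=True, node_label=node_label,
                                edge_label=edge_label, first_only=True))


# ---------------------------------------------------------------------------
# SING-style fingerprint index
# ---------------------------------------------------------------------------

def _node_features(g: nx.Graph, depth: int, node_label: NodeLabel,
                   edge_label: EdgeLabel) -> dict[Hashable, frozenset]:
    """Per node, the set of labeled simple-path signatures of length <= depth."""
    nlab = {v: repr(node_label(g.nodes[v])) for v in g.nodes}
    feats: dict[Hashable, set] = {v: set() for v in g.nodes}

    def walk(start, v, sig, visited, d):
        feats[start].add(sig)
        if d == depth:
            return
        for u in g[v]:
            if u in visited:
                continue
            walk(start, u, sig + (repr(edge_label(g.edges[v, u])), nlab[u]),
                 visited | {u}, d + 1)

    for v in g.nodes:
        walk(v, v, (nlab[v],), {v}, 0)
    return {v: frozenset(s) for v, s in feats.items()}


@dataclass
class SingIndex:
    """Inverted fingerprint index over a host-graph collection."""
    depth: int
    node_label: NodeLabel
    edge_label: EdgeLabel
    hosts: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)   # host id -> {node: frozenset}
    inverted: dict = field(default_factory=dict)   # feature -> set of host ids


def sing_build(hosts: Mapping[Hashable, nx.Graph] | Sequence[nx.Graph],
               depth: int = 3,
               node_label: NodeLabel = _default_node_label,
               edge_label: EdgeLabel = _default_edge_label) -> SingIndex:
    """Build the fingerprint index; refuses multigraphs."""
    if not isinstance(hosts, Mapping):
        hosts = dict(enumerate(hosts))
    idx = SingIndex(depth, node_label, edge_label)
    for hid in sorted(hosts, key=repr):
        g = hosts[hid]
        if g.is_multigraph():
            raise ValidationError("SING supports simple undirected graphs only "
                                  "(no parallel edges)")
        idx.hosts[hid] = g
        feats = _node_features(g, depth, node_label, edge_label)
        idx.features[hid] = feats
        for fs in feats.values():
            for f in fs:
                idx.inverted.setdefault(f, set()).add(hid)
    return idx


def sing_query(pattern: nx.Graph, index: SingIndex,
               induced: bool = False) -> dict[Hashable, list[Embedding]]:
    """All hosts embedding ``pattern``; identical to a naive matcher sweep.

    Filter soundness: a monomorphism maps every labeled simple path of the
    pattern onto an equally labeled simple path of the host, so any host
    (and any host node) lacking a pattern feature can be discarded without
    losing embeddings.
    """
    pf = _node_features(pattern, index.depth, index.node_label, index.edge_label)
    cands: set | None = None
    for fs in pf.values():
        for f in fs:
            hit = index.inverted.get(f, set())
            cands = hit.copy() if cands is None else cands & hit
            if not cands:
                return {}
    if cands is None:  # empty pattern
        cands = set(index.hosts)
    out: dict[Hashable, list[Embedding]] = {}
    for hid in sorted(cands, key=repr):
        hfeats = index.features[hid]
        node_cands = {p: {h for h, fs in hfeats.items() if pfs <= fs}
                      for p, pfs in pf.items()}
        if any(not c for c in node_cands.values()):
            continue
        emb = find_embeddings(pattern, index.hosts[hid], induced=induced,
                              node_label=index.node_label,
                              edge_label=index.edge_label,
                              candidates=node_cands)
        if emb:
            out[hid] = emb
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    """Partition of graph ids into isomorphism classes."""
    clusters: list[list]             # member ids, sorted per cluster
    representatives: list            # one member id per cluster
    labels: dict                     # id -> cluster index

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster(items: Mapping[Hashable, nx.Graph] | Sequence[nx.Graph],
            wl_iterations: int = 1,
            node_label: NodeLabel = _default_node_label,
            edge_label: EdgeLabel = _default_edge_label) -> Clustering:
    """Isomorphism clustering with a WL-hash prefilter.

    Graphs are bucketed by their WL digest, then compared exactly against
    one representative per cluster inside each bucket.  Because equal WL
    digests are implied by isomorphism, the prefilter never separates
    isomorphic graphs, and since isomorphism is an equivalence relation the
    representative linkage yields exactly the all-pairs partition -- the
    result is independent of ``wl_iterations``.
    """
    if not isinstance(items, Mapping):
        items = dict(enumerate(items))
    buckets: dict[str, list] = {}
    for gid in sorted(items, key=repr):
        d = canon.wl_hash(items[gid], wl_iterations, node_label, edge_label).digest
        buckets.setdefault(d, []).append(gid)
    clusters: list[list] = []
    reps: list = []
    labels: dict = {}
    for d in sorted(buckets):
        local_reps: list[int] = []  # indices into clusters
        for gid in buckets[d]:
            g = items[gid]
            for ci in local_reps:
                if is_isomorphic(g, items[reps[ci]], node_label, edge_label):
                    clusters[ci].append(gid)
                    labels[gid] = ci
                    break
            else:
                local_reps.append(len(clusters))
                labels[gid] = len(clusters)
                reps.append(gid)
                clusters.append([gid])
    return _sorted_clustering(items, clusters, reps, node_label, edge_label)


def _sorted_clustering(items, clusters, reps, node_label, edge_label) -> Clustering:
    """Stable output order: clusters sorted by representative certificate."""
    certs = [canon.certificate(items[r], node_label, edge_label) for r in reps]
    order = sorted(range(len(clusters)), key=lambda i: certs[i])
    new_clusters = [sorted(clusters[i], key=repr) for i in order]
    new_reps = [reps[i] for i in order]
    labels = {gid: ci for ci, members in enumerate(new_clusters) for gid in members}
    return Clustering(new_clusters, new_reps, labels)


def batch_cluster(items: Mapping[Hashable, nx.Graph] | Sequence[nx.Graph],
                  batch_size: int = 1000, wl_iterations: int = 1,
                  node_label: NodeLabel = _default_node_label,
                  edge_label: EdgeLabel = _default_edge_label) -> Clustering:
    """Cluster in batches and merge representatives; partition is identical
    to :func:`cluster` on the full input."""
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    if not isinstance(items, Mapping):
        items = dict(enumerate(items))
    ids = sorted(items, key=repr)
    merged_reps: list = []
    merged_clusters: list[list] = []
    for start in range(0, len(ids), batch_size):
        chunk = {gid: items[gid] for gid in ids[start:start + batch_size]}
        part = cluster(chunk, wl_iterations, node_label, edge_label)
        for members, rep in zip(part.clusters, part.representatives):
            for ci, mrep in enumerate(merged_reps):
                if canon.wl_hash(items[rep], wl_iterations, node_label, edge_label).digest == \
                        canon.wl_hash(items[mrep], wl_iterations, node_label, edge_label).digest and \
                        is_isomorphic(items[rep], items[mrep], node_label, edge_label):
                    merged_clusters[ci].extend(members)
                    break
            else:
                merged_reps.append(rep)
                merged_clusters.append(list(members))
    return _sorted_clustering(items, merged_clusters, merged_reps, node_label, edge_label)


# ---------------------------------------------------------------------------
# partition agreement measures
# ---------------------------------------------------------------------------

def partition_scores(labels_a: Mapping, labels_b: Mapping) -> dict[str, float]:
    """Purity, ARI and NMI of partition A against partition B (same keys)."""
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    keys = sorted(labels_a, key=repr)
    a = [labels_a[k] for k in keys]
    b = [labels_b[k] for k in keys]
    counts: dict = {}
    for x, y in zip(a, b):
        counts.setdefault(x, {}).setdefault(y, 0)
        counts[x][y] += 1
    purity = sum(max(c.values()) for c in counts.values()) / len(keys)
    return {
        "purity": purity,
        "ari": float(adjusted_rand_score(b, a)),
        "nmi": float(normalized_mutual_info_score(b, a)),
    }
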