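"""The 45-dimensional venation feature vector.

Per wing: one intersection-density feature (junctions per foreground
pixel), four population moments of vein segment arc lengths, sixteen
centrality moments (mean/variance/skewness/excess kurtosis of degree,
betweenness, closeness and eigenvector centrality pooled over nodes), and
twenty-four global network statistics (the same four moments of node
count, edge count, weighted diameter, weighted average path length,
clustering coefficient and degree assortativity across connected
components).  Skeletons of noisy images are routinely disconnected, so
per-component statistics give every image a well-defined distribution for
the global metrics.

Conventions: population (not sample) moments throughout; skewness and
excess kurtosis are 0 whenever the variance is 0; empty collections give
all-zero moments.  Shortest-path quantities (betweenness, closeness,
diameter, path length) are weighted by segment arc length; degree,
clustering and assortativity use unweighted structure.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import VeinGraph

__all__ = [
    "FEATURE_NAMES",
    "moments",
    "intersection_density",
    "segment_stats",
    "centrality_moments",
    "global_network_metrics",
    "extract_feature_vector",
]

_MOMENT_SUFFIXES = ("mean", "var", "skew", "kurt")
_CENTRALITIES = ("deg", "btw", "clo", "eig")
_GLOBALS = ("nodes", "edges", "diam", "apl", "cc", "assort")

FEATURE_NAMES: tuple[str, ...] = (
    ("density",)
    + tuple(f"seg_{s}" for s in _MOMENT_SUFFIXES)
    + tuple(f"cent_{c}_{s}" for c in _CENTRALITIES for s in _MOMENT_SUFFIXES)
    + tuple(f"glob_{g}_{s}" for g in _GLOBALS for s in _MOMENT_SUFFIXES)
)
assert len(FEATURE_NAMES) == 45


def moments(values: Sequence[float]) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and excess kurtosis, with
    degenerate conventions: all zero for an empty input; skewness and
    kurtosis zero when the variance vanishes."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        return (0.0, 0.0, 0.0, 0.0)
    mean = float(x.mean())
    d = x - mean
    m2 = float((d**2).mean())
    if m2 == 0.0:
        return (mean, 0.0, 0.0, 0.0)
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return (mean, m2, m3 / m2**1.5, m4 / m2**2 - 3.0)


def intersection_density(graph: VeinGraph, mask: np.ndarray) -> float:
    """Junction-kind nodes per foreground pixel of the vein mask."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("intersection density undefined for an empty mask")
    return graph.junction_count / area


def segment_stats(lengths: Sequence[float]) -> tuple[float, float, float, float]:
    """Population moments of vein segment arc lengths (pixels)."""
    return moments(lengths)


def _simple_weighted(graph: VeinGraph) -> nx.Graph:
    """Collapse the multigraph to a simple weighted graph for path-based
    quantities: parallel edges keep the minimum arc length, self-loops are
    dropped (they never lie on a shortest path)."""
    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(n.id)
    for e in graph.edges:
        if e.node_a == e.node_b:
            continue
        w = e.arc_length
        if g.has_edge(e.node_a, e.node_b):
            w = min(w, g[e.node_a][e.node_b]["weight"])
        g.add_edge(e.node_a, e.node_b, weight=w)
    return g


def _eigenvector_centrality(sub: nx.Graph) -> dict[int, float]:
    """Principal eigenvector of the component's unweighted adjacency
    (exact symmetric eigendecomposition; entries made non-negative and
    unit-Euclidean-normalized).  Isolated nodes score 0."""
    nodes = sorted(sub.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 0.0}
    a = nx.to_numpy_array(sub, nodelist=nodes, weight=None)
    evals, evecs = np.linalg.eigh(a)
    v = np.abs(evecs[:, -1])
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    return dict(zip(nodes, v.tolist()))


def centrality_moments(graph: VeinGraph) -> np.ndarray:
    """16 values: moments of degree, betweenness, closeness and eigenvector
    centrality pooled over all nodes.  Degree is the raw incident-edge
    count (self-loops count twice); betweenness is arc-length-weighted and
    normalized by (n-1)(n-2)/2 within each component; closeness uses the
    Wasserman-Faust component-size correction; eigenvector centrality is
    computed per component on the unweighted adjacency."""
    if not graph.nodes:
        return np.zeros(16)
    multi = graph.to_networkx()
    simple = _simple_weighted(graph)
    degree = [d for _, d in sorted(multi.degree())]

    btw: dict[int, float] = {}
    eig: dict[int, float] = {}
    for comp in nx.connected_components(simple):
        sub = simple.subgraph(comp)
        btw.update(nx.betweenness_centrality(sub, normalized=True, weight="weight"))
        eig.update(_eigenvector_centrality(sub))
    clo = nx.closeness_centrality(simple, distance="weight", wf_improved=True)

    order = sorted(n.id for n in graph.nodes)
    blocks = [
        degree,
        [btw[i] for i in order],
        [clo[i] for i in order],
        [eig[i] for i in order],
    ]
    return np.concatenate([moments(b) for b in blocks])


def global_network_metrics(graph: VeinGraph) -> np.ndarray:
    """24 values: moments across connected components of node count, edge
    count, weighted diameter, weighted average path length, clustering
    coefficient (transitivity; 0 without connected triples) and degree
    assortativity (0 when undefined)."""
    if not graph.nodes:
        return np.zeros(24)
    simple = _simple_weighted(graph)
    comps = [set(c) for c in nx.connected_components(simple)]

    per_edge_comp = np.zeros(len(comps))
    comp_of = {n: i for i, c in enumerate(comps) for n in c}
    for e in graph.edges:
        per_edge_comp[comp_of[e.node_a]] += 1

    nodes_c, edges_c, diam_c, apl_c, cc_c, assort_c = [], [], [], [], [], []
    for i, comp in enumerate(comps):
        sub = simple.subgraph(comp)
        n = len(comp)
        nodes_c.append(float(n))
        edges_c.append(float(per_edge_comp[i]))
        if n == 1:
            diam_c.append(0.0)
            apl_c.append(0.0)
        else:
            ecc = nx.eccentricity(sub, weight="weight")
            diam_c.append(float(max(ecc.values())))
            apl_c.append(float(nx.average_shortest_path_length(sub, weight="weight")))
        cc_c.append(float(nx.transitivity(sub)) if n >= 3 else 0.0)
        if n >= 2 and sub.number_of_edges() >= 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                a = nx.degree_assortativity_coefficient(sub)
            assort_c.append(0.0 if not np.isfinite(a) else float(a))
        else:
            assort_c.append(0.0)

    return np.concatenate(
        [moments(b) for b in (nodes_c, edges_c, diam_c, apl_c, cc_c, assort_c)]
    )


def extract_feature_vector(graph: VeinGraph, mask: np.ndarray) -> np.ndarray:
    """Concatenate density (1) + segment stats (4) + centrality moments
    (16) + global metrics (24) in the canonical :data:`FEATURE_NAMES`
    order."""
    vec = np.concatenate(
        [
            [intersection_density(graph, mask)],
            segment_stats(graph.segment_lengths()),
            centrality_moments(graph),
            global_network_metrics(graph),
        ]
    )
    assert vec.shape == (45,)
    return vec


def feature_table(
    ids: Sequence[str], vectors: Sequence[np.ndarray]
) -> pd.DataFrame:
    """Assemble a feature table with ``image_id`` plus the 45 canonical
    feature columns."""
    df = pd.DataFrame(np.asarray(vectors, dtype=np.float64), columns=list(FEATURE_NAMES))
    df.insert(0, "image_id", list(ids))
    return df
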