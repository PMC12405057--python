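"""Skeleton-to-graph conversion: hit-or-miss junction detection, centroid
merging, endpoint detection, and segment tracing.

Junction pixels are located with a bank of ternary 3x3 hit-or-miss kernels
(foreground-required / background-required / don't-care) built from 10 base
junction topologies and closed under 90-degree rotation.  Nearby junction
pixels are merged by union-find centroid averaging (default radius 4 px),
endpoints are skeleton pixels with exactly one neighbor, and vein segments
are traced pixel-by-pixel between nodes with the chain metric (1 per axial
step, sqrt(2) per diagonal step) as arc length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "KernelBank",
    "VeinGraph",
    "Node",
    "Edge",
    "build_kernel_bank",
    "detect_nodes",
    "merge_points",
    "trace_segments",
    "build_graph",
]

FG, BG, DC = 1, 0, 2  # ternary kernel entries: foreground / background / don't care

# Neighbor ring in circular order N, NE, E, SE, S, SW, W, NW and the
# corresponding (row, col) offsets.
_RING_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

# The 10 base junction topologies, given as arm positions on the neighbor
# ring (0 = N .. 7 = NW).  Arms are pairwise non-adjacent on the ring
# (angular gap >= 2): staircase pixels of thinned shallow curves always
# carry an adjacent neighbor pair, so this constraint is what separates
# genuine branch points from thinning artifacts.  Exactly four 3-arm
# topologies satisfy it up to 90-degree rotation (orthogonal T, diagonal T,
# two mixed Y forms); each appears in a strict variant (explicit background
# on the whole remaining ring, the classical hit-or-miss form) and a
# corner-tolerant variant (background required only at the non-arm
# orthogonal positions, don't-care at non-arm corners, catching junctions
# whose clusters carry an extra diagonal neighbor).  Together with the two
# 4-fold-symmetric crosses this gives the 10 bases.
_ORTHOGONAL_POSITIONS = (0, 2, 4, 6)
_BASE_ARM_SETS: list[tuple[str, tuple[int, ...], bool]] = [
    # (name, arms, strict background on ALL non-arm neighbors?)
    ("cross_orthogonal", (0, 2, 4, 6), True),
    ("cross_diagonal", (1, 3, 5, 7), True),
    ("t_orthogonal", (2, 4, 6), False),
    ("t_orthogonal_strict", (2, 4, 6), True),
    ("t_diagonal", (1, 3, 5), False),
    ("t_diagonal_strict", (1, 3, 5), True),
    ("y_mixed_a", (0, 2, 5), False),
    ("y_mixed_a_strict", (0, 2, 5), True),
    ("y_mixed_b", (0, 3, 5), False),
    ("y_mixed_b_strict", (0, 3, 5), True),
]


@dataclass(frozen=True)
class KernelBank:
    """Distinct ternary 3x3 hit-or-miss kernels, closed under 90-degree rotation."""

    kernels: tuple[tuple[tuple[int, ...], ...], ...]

    def __len__(self) -> int:
        return len(self.kernels)

    def as_arrays(self) -> list[np.ndarray]:
        return [np.array(k, dtype=np.int8) for k in self.kernels]


def _kernel_from_arms(arms: Iterable[int], strict: bool) -> np.ndarray:
    arms = set(arms)
    k = np.full((3, 3), BG, dtype=np.int8)
    if not strict:
        # corner-tolerant: don't-care at non-arm diagonal positions
        for a in range(8):
            if a not in _ORTHOGONAL_POSITIONS:
                dr, dc = _RING_OFFSETS[a]
                k[1 + dr, 1 + dc] = DC
    k[1, 1] = FG
    for a in arms:
        dr, dc = _RING_OFFSETS[a]
        k[1 + dr, 1 + dc] = FG
    return k


def build_kernel_bank() -> KernelBank:
    """Expand the 10 base junction patterns by all 90-degree rotations and
    drop exact duplicates.  The two crosses are 4-fold symmetric (1 kernel
    each); the eight asymmetric patterns contribute 4 kernels each."""
    seen: dict[bytes, np.ndarray] = {}
    for _name, arms, strict in _BASE_ARM_SETS:
        base = _kernel_from_arms(arms, strict)
        for rot in range(4):
            k = np.rot90(base, rot)
            seen.setdefault(k.tobytes(), k)
    kernels = tuple(tuple(tuple(int(v) for v in row) for row in k) for k in seen.values())
    return KernelBank(kernels=kernels)


def _shifted_neighbors(skel: np.ndarray) -> np.ndarray:
    """Stack of the 9 pattern positions for every pixel: index [dr+1, dc+1]."""
    p = np.pad(skel, 1, mode="constant").astype(bool)
    h, w = skel.shape
    out = np.empty((3, 3, h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out[dr + 1, dc + 1] = p[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return out


def detect_nodes(
    skel: np.ndarray, bank: KernelBank | None = None
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Locate raw junction pixels (hit-or-miss match against any bank
    kernel) and endpoint pixels (exactly one 8-neighbor) on a skeleton."""
    skel = np.asarray(skel, dtype=bool)
    if bank is None:
        bank = build_kernel_bank()
    if skel.size == 0 or not skel.any():
        return [], []
    nb = _shifted_neighbors(skel)
    junction = np.zeros_like(skel)
    for k in bank.as_arrays():
        match = skel.copy()
        for i in range(3):
            for j in range(3):
                if k[i, j] == FG:
                    match &= nb[i, j]
                elif k[i, j] == BG:
                    match &= ~nb[i, j]
        junction |= match
    neighbor_count = nb.sum(axis=(0, 1)) - skel.astype(int)
    endpoint = skel & (neighbor_count == 1)
    return (
        [tuple(map(int, p)) for p in np.argwhere(junction)],
        [tuple(map(int, p)) for p in np.argwhere(endpoint)],
    )


def branch_pixels(skel: np.ndarray) -> list[tuple[int, int]]:
    """Skeleton pixels with crossing number >= 3: at least three 0->1
    transitions around the 8-neighbor ring, the classical branch-point
    criterion.  The hit-or-miss bank matches the subset of these whose
    arms are pairwise non-adjacent on the ring; the remainder (arms that
    abut, e.g. very shallow forks) must still anchor segment tracing or
    their branches would be orphaned."""
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        return []
    nb = _shifted_neighbors(skel)
    ring = [nb[1 + dr, 1 + dc] for dr, dc in _RING_OFFSETS]
    ring.append(ring[0])
    crossings = sum((~ring[i] & ring[i + 1]) for i in range(8))
    return [tuple(map(int, p)) for p in np.argwhere(skel & (crossings >= 3))]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_points(
    points: Sequence[tuple[float, float]], radius: float = 4.0
) -> list[tuple[float, float]]:
    """Merge points by centroid averaging: points within ``radius``
    (Euclidean) are linked, connected groups (transitive closure) are each
    replaced by their centroid.  Result sorted by (row, col)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    uf = _UnionFind(n)
    for i in range(n):
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        for j in np.nonzero(d <= radius)[0]:
            uf.union(i, i + 1 + int(j))
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    centroids = [tuple(pts[idx].mean(axis=0)) for idx in groups.values()]
    return sorted((float(r), float(c)) for r, c in centroids)


@dataclass(frozen=True)
class Node:
    id: int
    coord: tuple[float, float]  # (row, col)
    kind: str  # "junction" | "endpoint"


@dataclass(frozen=True)
class Edge:
    node_a: int
    node_b: int
    pixel_path: tuple[tuple[int, int], ...]
    arc_length: float


@dataclass
class VeinGraph:
    """Node/edge representation of a vein skeleton.  Parallel edges and
    self-loops are permitted; node ids follow (row, col) order."""

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    @property
    def junction_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    def degree_sum(self) -> int:
        total = 0
        for e in self.edges:
            total += 2  # self-loops contribute 2 to their single endpoint
        return total

    def segment_lengths(self) -> list[float]:
        return [e.arc_length for e in self.edges]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, coord=n.coord, kind=n.kind)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, weight=e.arc_length)
        return g

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": [
                {"id": n.id, "coord": list(n.coord), "kind": n.kind} for n in self.nodes
            ],
            "edges": [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "pixel_path": [list(p) for p in e.pixel_path],
                    "arc_length": e.arc_length,
                }
                for e in self.edges
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "VeinGraph":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        payload = json.loads(text)
        nodes = [Node(d["id"], tuple(d["coord"]), d["kind"]) for d in payload["nodes"]]
        edges = [
            Edge(
                d["node_a"],
                d["node_b"],
                tuple(tuple(p) for p in d["pixel_path"]),
                d["arc_length"],
            )
            for d in payload["edges"]
        ]
        return cls(nodes=nodes, edges=edges)


_STEPS = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]


def _path_length(path: Sequence[tuple[int, int]]) -> float:
    total = 0.0
    for (r1, c1), (r2, c2) in zip(path[:-1], path[1:]):
        total += np.sqrt(2.0) if (r1 != r2 and c1 != c2) else 1.0
    return float(total)


# Self-loops this short are internal connections of a merged junction
# cluster, not vein segments.
_TRIVIAL_LOOP_PIXELS = 3


def trace_segments(
    skel: np.ndarray,
    merged_junctions: Sequence[tuple[float, float]],
    endpoints: Sequence[tuple[int, int]],
    raw_junction_pixels: Sequence[tuple[int, int]] | None = None,
    merge_radius: float = 4.0,
) -> tuple[list[Node], list[Edge]]:
    """Walk the skeleton between node pixels and record each vein segment.

    Every raw junction pixel maps to the nearest merged-junction centroid
    (its union-find group); endpoint pixels are their own nodes.  Isolated
    cycles with no node receive a synthetic node at their topmost-leftmost
    pixel and a self-loop edge; isolated single pixels become degree-0
    endpoint nodes.
    """
    skel = np.asarray(skel, dtype=bool)
    if raw_junction_pixels is None:
        raw_junction_pixels, _ = detect_nodes(skel)

    # node table in (row, col) order: junctions first by coordinate, then endpoints
    node_records: list[tuple[tuple[float, float], str]] = [
        (tuple(c), "junction") for c in merged_junctions
    ] + [((float(r), float(c)), "endpoint") for r, c in endpoints]
    node_records.sort(key=lambda rec: rec[0])
    nodes = [Node(i, coord, kind) for i, (coord, kind) in enumerate(node_records)]
    coord_to_id = {n.coord: n.id for n in nodes}

    # raw junction pixel -> merged node id (nearest centroid within reach)
    pixel_node: dict[tuple[int, int], int] = {}
    if merged_junctions and raw_junction_pixels:
        cents = np.asarray(merged_junctions, dtype=np.float64)
        for r, c in raw_junction_pixels:
            d = np.hypot(cents[:, 0] - r, cents[:, 1] - c)
            k = int(np.argmin(d))
            pixel_node[(int(r), int(c))] = coord_to_id[tuple(cents[k])]
    for r, c in endpoints:
        pixel_node[(int(r), int(c))] = coord_to_id[(float(r), float(c))]

    h, w = skel.shape

    def skel_neighbors(px: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = px
        out = []
        for dr, dc in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                out.append((rr, cc))
        return out

    visited: set[tuple[int, int]] = set()
    edges: list[Edge] = []
    direct_seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    def add_edge(a: int, b: int, path: list[tuple[int, int]]) -> None:
        length = _path_length(path)
        if a == b and len(path) <= _TRIVIAL_LOOP_PIXELS:
            # junction-cluster internal hop, not a vein segment; release its
            # pixels so a real segment entering through them can be traced
            visited.difference_update(path[1:-1])
            return
        edges.append(Edge(min(a, b), max(a, b), tuple(path), length))

    for start_px in sorted(pixel_node):
        a = pixel_node[start_px]
        for q in skel_neighbors(start_px):
            if q in pixel_node:
                if pixel_node[q] != a:
                    key = (min(start_px, q), max(start_px, q))
                    if key not in direct_seen:
                        direct_seen.add(key)
                        add_edge(a, pixel_node[q], [start_px, q])
                continue
            if q in visited:
                continue
            path = [start_px, q]
            visited.add(q)
            prev, cur = start_px, q
            while True:
                nbrs = skel_neighbors(cur)
                # a pixel of the starting node terminates the walk only once
                # the path is long enough to be a genuine loop; otherwise the
                # walk is still skirting its own junction cluster
                node_nbrs = [
                    p
                    for p in nbrs
                    if p in pixel_node
                    and p != prev
                    and (pixel_node[p] != a or len(path) > _TRIVIAL_LOOP_PIXELS)
                ]
                if node_nbrs:
                    end_px = min(node_nbrs)
                    path.append(end_px)
                    add_edge(a, pixel_node[end_px], path)
                    break
                free = [p for p in nbrs if p not in visited and p not in pixel_node and p != prev]
                if not free:
                    # dangling path (should end at an endpoint node; guard anyway)
                    break
                # prefer a continuation that is not adjacent to the previous
                # pixel: neighbors touching prev are corner pixels of another
                # branch, and stepping onto them U-turns the walk
                ahead = [
                    p
                    for p in free
                    if max(abs(p[0] - prev[0]), abs(p[1] - prev[1])) > 1
                ]
                nxt = min(ahead) if ahead else min(free)
                path.append(nxt)
                visited.add(nxt)
                prev, cur = cur, nxt

    # leftover pixels: isolated cycles, lone dots, and redundant staircase
    # pixels skirted by a walk.  Only components with no contact to the
    # traced structure are real; the rest are debris of traced paths.
    remaining = {tuple(map(int, p)) for p in np.argwhere(skel)} - visited - set(pixel_node)
    traced = visited | set(pixel_node)
    while remaining:
        start_px = min(remaining)
        # flood-fill the component
        comp = {start_px}
        stack = [start_px]
        while stack:
            cur = stack.pop()
            for p in skel_neighbors(cur):
                if p in remaining and p not in comp:
                    comp.add(p)
                    stack.append(p)
        remaining -= comp
        if any(p in traced for px in comp for p in skel_neighbors(px)):
            continue  # redundant offshoot of an already-traced path
        coord = (float(start_px[0]), float(start_px[1]))
        kind = "endpoint" if len(comp) == 1 else "junction"
        node_id = len(nodes)
        nodes.append(Node(node_id, coord, kind))
        if len(comp) > 1:
            # trace the cycle from the synthetic node back to itself
            path = [start_px]
            prev: tuple[int, int] | None = None
            cur = start_px
            while True:
                nbrs = [p for p in skel_neighbors(cur) if p in comp]
                free = [p for p in nbrs if p != prev and p not in path[1:]]
                if not free or (len(path) > 2 and start_px in [p for p in nbrs if p != prev]):
                    path.append(start_px)
                    break
                nxt = min(free)
                path.append(nxt)
                prev, cur = cur, nxt
            edges.append(Edge(node_id, node_id, tuple(path), _path_length(path)))

    # renumber so ids follow (row, col) order including synthetic nodes
    order = sorted(range(len(nodes)), key=lambda i: nodes[i].coord)
    remap = {old: new for new, old in enumerate(order)}
    nodes = [Node(remap[n.id], n.coord, n.kind) for n in nodes]
    nodes.sort(key=lambda n: n.id)
    edges = [
        Edge(
            min(remap[e.node_a], remap[e.node_b]),
            max(remap[e.node_a], remap[e.node_b]),
            e.pixel_path,
            e.arc_length,
        )
        for e in edges
    ]
    edges.sort(key=lambda e: (e.node_a, e.node_b, e.pixel_path))
    return nodes, edges


def build_graph(skel: np.ndarray, merge_radius: float = 4.0) -> VeinGraph:
    """Full skeleton-to-graph conversion: detect nodes, merge junction
    pixels within ``merge_radius``, trace segments.  Deterministic."""
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        return VeinGraph()
    bank = build_kernel_bank()
    raw_junctions, endpoints = detect_nodes(skel, bank)
    # crossing-number branch pixels the bank does not cover still anchor
    # tracing (and merge into nearby junction clusters)
    raw_junctions = sorted(set(raw_junctions) | set(branch_pixels(skel)))
    merged = merge_points(raw_junctions, radius=merge_radius) if raw_junctions else []
    nodes, edges = trace_segments(
        skel, merged, endpoints, raw_junction_pixels=raw_junctions, merge_radius=merge_radius
    )
    return VeinGraph(nodes=nodes, edges=edges)
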