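"""Canal centerline graph: skeletonization, canal counting, and the
connecting/accessory canal inventory.

The lumen mask is thinned to a one-voxel curve skeleton which is converted to
a graph (junction/endpoint nodes, centerline-chain edges with per-voxel
radii from the Euclidean distance transform).  Short voxelization spurs are
pruned with a radius-adaptive rule.  Exterior openings are attached as
explicit exit nodes from the lumen-background contact components, so every
exit lies on the lumen-exterior interface even though medial-axis thinning
retracts endpoints by about one local radius.

Edge roles:

* main - wide edges (or terminal segments of physiological exits) on some
  chamber-to-physiological-foramen route; these carry the RCC digits;
* accessory - terminal branches to sub-0.2 mm openings;
* connecting - thin edges whose both ends attach to the main system: type L
  (loop) when the two attachments lie on one canal run, type C
  (communicating) when the in-main path between them crosses a junction;
* spur - anything else (ignored).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "CanalGraph",
    "ExitRecord",
    "CanalGraphError",
    "skeletonize_canals",
    "count_canals_at_plane",
    "classify_connecting_canals",
    "find_accessory_canals",
]

log = logging.getLogger(__name__)

PRUNE_LENGTH_MM = 0.1
CALIBER_MM = 0.2          # main-canal caliber threshold (matches the foramen rule)

_STRUCT26 = ndimage.generate_binary_structure(3, 3)
_OFFSETS26 = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


class CanalGraphError(ValueError):
    pass


@dataclass
class ExitRecord:
    """One lumen-exterior opening attached to the skeleton."""

    exit_id: int
    node: int                       # graph node id (role 'exit')
    centroid_idx: np.ndarray        # (z, y, x) in full-volume voxels
    opening_diameter_mm: float
    n_contact_voxels: int


@dataclass
class CanalGraph:
    """Skeleton graph of the canal system (positions in full-volume voxels)."""

    g: nx.Graph
    voxel_size_mm: float
    exits: list[ExitRecord] = field(default_factory=list)
    chamber_node: int | None = None

    # ---- basic queries ---------------------------------------------------

    def node_pos(self, n: int) -> np.ndarray:
        return self.g.nodes[n]["pos"]

    def edge_voxels(self, u: int, v: int) -> np.ndarray:
        return self.g.edges[u, v]["voxels"]

    def skeleton_at_slice(self, k: int, kinds: set[str] | None = None) -> np.ndarray:
        """(n, 2) array of (y, x) skeleton voxels at slice ``k`` (optionally
        restricted to edge kinds)."""
        pts = []
        for u, v, attrs in self.g.edges(data=True):
            if kinds is not None and attrs.get("kind") not in kinds:
                continue
            vox = attrs["voxels"]
            if len(vox):
                sel = vox[:, 0] == k
                if sel.any():
                    pts.append(vox[sel, 1:])
            # node positions are not part of any chain; include both ends
            for n in (u, v):
                pos = np.round(self.g.nodes[n]["pos"]).astype(int)
                if pos[0] == k:
                    pts.append(pos[None, 1:])
        if not pts:
            return np.empty((0, 2), dtype=int)
        return np.concatenate(pts, axis=0)

    def terminal_path(self, exit_id: int) -> np.ndarray:
        """Centerline positions junction -> exit for one exterior opening.

        Walks from the exit node up through pass-through nodes until the
        first junction (degree >= 3) or the chamber; the path ends on the
        lumen-exterior interface (the exit centroid).
        """
        edges = self.terminal_edges(exit_id)
        if not edges:
            return np.atleast_2d(self.node_pos(self.exits[exit_id].node))
        positions = []
        for a, b in edges:
            positions.append(np.atleast_2d(self.node_pos(a)))
            vox = self.edge_voxels(a, b).astype(float)
            if len(vox):
                positions.append(_oriented(vox, self.node_pos(a)))
        positions.append(np.atleast_2d(self.node_pos(edges[-1][1])))
        path = np.concatenate(positions, axis=0)[::-1]   # junction -> exit
        return _deduplicate(path)

    def terminal_edges(self, exit_id: int) -> list[tuple[int, int]]:
        """Graph edges of the terminal branch belonging to one exit."""
        rec = self.exits[exit_id]
        edges = []
        prev = None
        current = rec.node
        while True:
            neighbors = [n for n in self.g.neighbors(current) if n != prev]
            if not neighbors:
                break
            nxt = neighbors[0]
            edges.append((current, nxt))
            prev, current = current, nxt
            if self.g.degree(current) >= 3 or current == self.chamber_node:
                break
        return edges

    # ---- role assignment -------------------------------------------------

    def assign_roles(self, physiological_exits: set[int], caliber_mm: float = CALIBER_MM):
        """Label every edge main / accessory / connecting / spur.

        ``physiological_exits`` are exit ids already classified by foramen
        metrology (wide diameter >= the caliber threshold).
        """
        g = self.g
        for _, _, attrs in g.edges(data=True):
            attrs["kind"] = "spur"

        phys_terminal: set[frozenset] = set()
        acc_terminal: set[frozenset] = set()
        for rec in self.exits:
            bucket = phys_terminal if rec.exit_id in physiological_exits else acc_terminal
            for u, v in self.terminal_edges(rec.exit_id):
                bucket.add(frozenset((u, v)))

        def in_h(u, v, attrs) -> bool:
            if frozenset((u, v)) in phys_terminal:
                return True
            if frozenset((u, v)) in acc_terminal:
                return False
            return attrs["mean_diameter_mm"] >= caliber_mm * 0.9

        h = nx.Graph(
            (u, v) for u, v, attrs in g.edges(data=True) if in_h(u, v, attrs)
        )
        phys_nodes = {self.exits[i].node for i in physiological_exits}
        up, down = set(), set()
        if self.chamber_node is not None and self.chamber_node in h:
            up = set(nx.node_connected_component(h, self.chamber_node))
        for n in phys_nodes:
            if n in h:
                down |= set(nx.node_connected_component(h, n))
        main_nodes = up & down if up else down
        for u, v, attrs in g.edges(data=True):
            if frozenset((u, v)) in acc_terminal:
                attrs["kind"] = "accessory"
            elif in_h(u, v, attrs) and u in main_nodes and v in main_nodes:
                attrs["kind"] = "main"
        # connecting: thin leftover edges bridging two main nodes
        for u, v, attrs in g.edges(data=True):
            if attrs["kind"] == "spur" and u in main_nodes and v in main_nodes:
                attrs["kind"] = "connecting"
        return main_nodes

    # ---- export ----------------------------------------------------------

    def to_json_dict(self) -> dict:
        nodes = [
            {
                "id": int(n),
                "pos": [float(x) for x in attrs["pos"]],
                "radius_mm": float(attrs.get("radius_mm", 0.0)),
                "role": attrs.get("role", ""),
            }
            for n, attrs in self.g.nodes(data=True)
        ]
        edges = [
            {
                "u": int(u),
                "v": int(v),
                "length_mm": float(attrs["length_mm"]),
                "mean_radius_mm": float(attrs["mean_radius_mm"]),
                "kind": attrs.get("kind", ""),
            }
            for u, v, attrs in self.g.edges(data=True)
        ]
        return {"voxel_size_mm": self.voxel_size_mm, "nodes": nodes, "edges": edges}

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=1))
        return path

    def save_edge_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["u,v,length_mm,mean_radius_mm,kind"]
        for u, v, attrs in self.g.edges(data=True):
            lines.append(
                f"{u},{v},{attrs['length_mm']:.4f},{attrs['mean_radius_mm']:.4f},"
                f"{attrs.get('kind', '')}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


def _deduplicate(path: np.ndarray) -> np.ndarray:
    if len(path) < 2:
        return path
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.any(np.diff(path, axis=0) != 0, axis=1)
    return path[keep]


# -- skeleton -> graph -----------------------------------------------------

def _build_graph_from_skeleton(skel: np.ndarray, offset: np.ndarray, radius_map: np.ndarray,
                               voxel_size_mm: float) -> nx.Graph:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nvox = len(coords)
    neighbors: list[list[int]] = [[] for _ in range(nvox)]
    for i, c in enumerate(coords):
        for off in _OFFSETS26:
            key = tuple(c + off)
            j = index.get(key)
            if j is not None:
                neighbors[i].append(j)
    degree = np.array([len(n) for n in neighbors])

    is_node = degree != 2
    if not is_node.any():       # pure cycle: promote an arbitrary voxel
        is_node[0] = True

    # cluster adjacent node voxels into single graph nodes
    node_cluster = np.full(nvox, -1, dtype=int)
    n_clusters = 0
    for i in np.flatnonzero(is_node):
        if node_cluster[i] >= 0:
            continue
        stack = [i]
        node_cluster[i] = n_clusters
        while stack:
            j = stack.pop()
            for kk in neighbors[j]:
                if is_node[kk] and node_cluster[kk] < 0:
                    node_cluster[kk] = n_clusters
                    stack.append(kk)
        n_clusters += 1

    g = nx.Graph()
    cluster_members: list[list[int]] = [[] for _ in range(n_clusters)]
    for i in np.flatnonzero(is_node):
        cluster_members[node_cluster[i]].append(i)
    for cid, members in enumerate(cluster_members):
        pts = coords[members] + offset
        radius = float(np.max(radius_map[tuple(coords[members].T)]) * voxel_size_mm)
        role = "junction" if max(degree[m] for m in members) >= 3 else "endpoint"
        g.add_node(cid, pos=pts.mean(axis=0), radius_mm=radius, role=role)

    # trace chains between node clusters
    visited = np.zeros(nvox, dtype=bool)
    next_id = [n_clusters]

    def chain_radius(chain: list[int]) -> float:
        # median over the interior of the chain: EDT values near junctions are
        # inflated by the adjoining wide canal and would bias a mean upward
        radii = radius_map[tuple(coords[chain].T)]
        if len(radii) >= 8:
            q = len(radii) // 4
            radii = radii[q:-q]
        return float(np.median(radii) * voxel_size_mm)

    def _raw_edge(c0: int, c1: int, chain: list[int]):
        pts = coords[chain] + offset if chain else np.empty((0, 3), dtype=int)
        full = [coords[m] for m in chain]
        seq = np.array(
            [g.nodes[c0]["pos"] - offset] + full + [g.nodes[c1]["pos"] - offset]
        )
        length = float(np.sum(np.linalg.norm(np.diff(seq, axis=0), axis=1)) * voxel_size_mm)
        mean_r = chain_radius(chain) if chain else float(
            (g.nodes[c0]["radius_mm"] + g.nodes[c1]["radius_mm"]) / 2
        )
        g.add_edge(
            c0, c1, voxels=pts, length_mm=length,
            mean_radius_mm=mean_r, mean_diameter_mm=2 * mean_r,
        )

    def _midpoint_node(chain_voxel: int) -> int:
        nid = next_id[0]
        next_id[0] += 1
        g.add_node(
            nid,
            pos=(coords[chain_voxel] + offset).astype(float),
            radius_mm=float(radius_map[tuple(coords[chain_voxel])] * voxel_size_mm),
            role="pass",
        )
        return nid

    def add_edge(c0: int, c1: int, chain: list[int]):
        # parallel chains and self-loops (genuine canal loops) must survive in
        # a simple Graph: split the chain with artificial pass-through nodes
        if c0 == c1:
            if len(chain) < 2:
                return
            i1, i2 = len(chain) // 3, 2 * len(chain) // 3
            if i1 == 0 or i2 <= i1:
                return
            m1, m2 = _midpoint_node(chain[i1]), _midpoint_node(chain[i2])
            _raw_edge(c0, m1, chain[:i1])
            _raw_edge(m1, m2, chain[i1 + 1: i2])
            _raw_edge(m2, c1, chain[i2 + 1:])
            return
        if g.has_edge(c0, c1):
            if not chain:
                return
            mid = len(chain) // 2
            m1 = _midpoint_node(chain[mid])
            _raw_edge(c0, m1, chain[:mid])
            _raw_edge(m1, c1, chain[mid + 1:])
            return
        _raw_edge(c0, c1, chain)

    for i in range(nvox):
        if not is_node[i]:
            continue
        for j in neighbors[i]:
            if is_node[j]:
                if node_cluster[i] != node_cluster[j]:
                    add_edge(node_cluster[i], node_cluster[j], [])
                continue
            if visited[j]:
                continue
            chain = []
            prev, cur = i, j
            while True:
                visited[cur] = True
                chain.append(cur)
                nxts = [k for k in neighbors[cur] if k != prev]
                if not nxts:
                    # dangling chain end without a node voxel (shouldn't happen)
                    break
                node_nxts = [k for k in nxts if is_node[k]]
                if node_nxts:
                    add_edge(node_cluster[i], node_cluster[node_nxts[0]], chain)
                    break
                nxt = next((k for k in nxts if not visited[k]), None)
                if nxt is None:
                    break
                prev, cur = cur, nxt
    return g


def _simplify_degree2(g: nx.Graph, protected: set[int]) -> None:
    """Merge chains through pass-through nodes left behind by pruning."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if n in protected or g.degree(n) != 2:
                continue
            (a, b) = list(g.neighbors(n))
            if a == b or g.has_edge(a, b):
                continue
            e1, e2 = g.edges[a, n], g.edges[n, b]
            vox = np.concatenate([
                _oriented(e1["voxels"], g.nodes[a]["pos"]),
                np.atleast_2d(np.round(g.nodes[n]["pos"]).astype(int)),
                _oriented(e2["voxels"], g.nodes[n]["pos"]),
            ])
            length = e1["length_mm"] + e2["length_mm"]
            w = (e1["mean_radius_mm"] * e1["length_mm"] + e2["mean_radius_mm"] * e2["length_mm"])
            mean_r = w / length if length > 0 else e1["mean_radius_mm"]
            g.remove_node(n)
            g.add_edge(a, b, voxels=vox, length_mm=length,
                       mean_radius_mm=mean_r, mean_diameter_mm=2 * mean_r)
            changed = True
            break


def _oriented(vox: np.ndarray, start_pos: np.ndarray) -> np.ndarray:
    if len(vox) < 2:
        return vox
    if np.linalg.norm(vox[0] - start_pos) > np.linalg.norm(vox[-1] - start_pos):
        return vox[::-1]
    return vox


def skeletonize_canals(
    lumen: np.ndarray,
    voxel_size_mm: float,
    background: np.ndarray | None = None,
    prune_length_mm: float = PRUNE_LENGTH_MM,
) -> CanalGraph:
    """Skeletonize the lumen and return its centerline graph.

    ``background`` (exterior, non-tooth voxels) is used to attach explicit
    exit nodes at the lumen-exterior contact components; without it, no exits
    are annotated.  Spurious leaf branches shorter than
    ``max(prune_length_mm, 2 x local radius)`` that do not lead to an exit
    are pruned.
    """
    if not lumen.any():
        raise CanalGraphError("empty lumen mask: nothing to skeletonize")
    bbox = ndimage.find_objects(lumen.astype(np.uint8))[0]
    pad = 2
    sl = tuple(
        slice(max(0, s.start - pad), min(dim, s.stop + pad))
        for s, dim in zip(bbox, lumen.shape)
    )
    offset = np.array([s.start for s in sl])
    sub = lumen[sl]
    skel = skeletonize(sub)
    if not skel.any():
        # degenerate case: thinning can annihilate perfectly symmetric tubes
        # (no uniquely central voxel); fall back to per-slice component
        # centroids, which is the exact axis for such shapes
        skel = np.zeros_like(sub)
        for k in range(sub.shape[0]):
            comp, n = ndimage.label(sub[k], structure=np.ones((3, 3), bool))
            for cid in range(1, n + 1):
                pts = np.argwhere(comp == cid)
                cy, cx = pts.mean(axis=0)
                j = int(np.argmin((pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2))
                skel[k, pts[j, 0], pts[j, 1]] = True
    radius_map = ndimage.distance_transform_edt(sub)
    g = _build_graph_from_skeleton(skel, offset, radius_map, voxel_size_mm)

    graph = CanalGraph(g=g, voxel_size_mm=voxel_size_mm)

    # exits from lumen-exterior contact
    if background is not None:
        contact = np.zeros_like(lumen)
        for axis in range(3):
            for shift in (-1, 1):
                rolled = np.roll(background, shift, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                rolled[tuple(edge)] = True   # volume border counts as exterior
                contact |= lumen & rolled
        comp, n = ndimage.label(contact, structure=_STRUCT26)
        node_ids = list(g.nodes)
        node_pos = np.array([g.nodes[n_]["pos"] for n_ in node_ids]) if node_ids else None
        for cid in range(1, n + 1):
            vox = np.argwhere(comp == cid)
            centroid = vox.mean(axis=0)
            area_px = len(vox)
            diameter = 2.0 * np.sqrt(area_px / np.pi) * voxel_size_mm
            # attach to the nearest endpoint-ish node
            d = np.linalg.norm(node_pos - centroid, axis=1)
            target = node_ids[int(np.argmin(d))]
            new_id = max(g.nodes) + 1
            g.add_node(new_id, pos=centroid, radius_mm=diameter / 2, role="exit")
            line = np.linspace(g.nodes[target]["pos"], centroid,
                               max(2, int(np.ceil(d.min())) + 1))
            g.add_edge(
                target, new_id,
                voxels=np.round(line).astype(int),
                length_mm=float(d.min() * voxel_size_mm),
                mean_radius_mm=diameter / 2,
                mean_diameter_mm=diameter,
            )
            graph.exits.append(
                ExitRecord(len(graph.exits), new_id, centroid, diameter, area_px)
            )

    exit_nodes = {rec.node for rec in graph.exits}
    _prune(g, exit_nodes, prune_length_mm)
    _simplify_degree2(g, protected=exit_nodes)

    # chamber = topmost remaining node
    if g.number_of_nodes():
        chamber = min(g.nodes, key=lambda n_: g.nodes[n_]["pos"][0])
        g.nodes[chamber]["role"] = "chamber"
        graph.chamber_node = chamber
    # re-point exit ids after pruning (nodes protected, so ids survive)
    return graph


def _prune(g: nx.Graph, protected: set[int], prune_length_mm: float) -> None:
    for _ in range(4):
        removed = False
        for n in list(g.nodes):
            if n in protected or g.degree(n) != 1:
                continue
            (nbr,) = g.neighbors(n)
            attrs = g.edges[n, nbr]
            limit = max(prune_length_mm, 2.0 * g.nodes[nbr].get("radius_mm", 0.0))
            if attrs["length_mm"] < limit:
                g.remove_node(n)
                removed = True
        if not removed:
            break
        _simplify_degree2(g, protected)


# -- canal counting --------------------------------------------------------

def count_canals_at_plane(
    lumen: np.ndarray,
    plane_index: int,
    graph: CanalGraph | None = None,
    side=None,
    min_area_px: int = 0,
) -> int:
    """Number of root canals crossing an axial plane.

    Without a graph this is the plain 2D (8-connectivity) connected-component
    count of the lumen cross-section, optionally dropping components below
    ``min_area_px``.  With a graph, a component counts only when it contains
    a main-system centerline voxel at this slice (excluding components
    entirely attributable to accessory or connecting canals, and blind
    diverticula that reach no foramen).  ``side`` restricts counting to one
    root's territory: a callable mapping an (y, x) point to True/False.
    """
    if not 0 <= plane_index < lumen.shape[0]:
        raise CanalGraphError(f"plane {plane_index} outside the volume")
    section = lumen[plane_index]
    if not section.any():
        return 0
    comp, n = ndimage.label(section, structure=np.ones((3, 3), dtype=bool))
    if graph is None:
        count = 0
        for cid in range(1, n + 1):
            mask = comp == cid
            if mask.sum() < min_area_px:
                continue
            if side is not None:
                cy, cx = ndimage.center_of_mass(mask)
                if not side(np.array([cy, cx])):
                    continue
            count += 1
        return count

    main_pts = graph.skeleton_at_slice(plane_index, kinds={"main"})
    if side is not None and len(main_pts):
        keep = np.array([bool(side(p)) for p in main_pts])
        main_pts = main_pts[keep]
    count = 0
    for cid in range(1, n + 1):
        mask = comp == cid
        has_main = any(mask[y, x] for y, x in main_pts)
        if has_main:
            count += 1
    return count


# -- canal inventory -------------------------------------------------------

def classify_connecting_canals(
    graph: CanalGraph,
    third_of,
    side=None,
) -> list[dict]:
    """Type and third of every connecting canal edge.

    ``third_of`` maps a world-z (mm) to a third name; ``side`` (optional)
    maps a (y, x) point to a root label.  Type L when the in-main path
    between the two attachment nodes crosses no main junction (the canal
    leaves and re-enters the same canal run); type C otherwise.
    """
    g = graph.g
    main = nx.Graph(
        (u, v) for u, v, attrs in g.edges(data=True) if attrs.get("kind") == "main"
    )
    out = []
    for u, v, attrs in g.edges(data=True):
        if attrs.get("kind") != "connecting":
            continue
        ctype = "C"
        if u in main and v in main:
            try:
                path = nx.shortest_path(main, u, v)
                junctions = [n for n in path[1:-1] if main.degree(n) >= 3]
                ctype = "L" if not junctions else "C"
            except nx.NetworkXNoPath:
                ctype = "C"
        vox = attrs["voxels"]
        mid = vox[len(vox) // 2] if len(vox) else (
            (graph.node_pos(u) + graph.node_pos(v)) / 2
        )
        entry = {
            "type": ctype,
            "mid_index": [float(x) for x in np.asarray(mid, dtype=float)],
            "third": third_of(float(mid[0]) * graph.voxel_size_mm),
        }
        if side is not None:
            entry["root"] = side(np.asarray(mid, dtype=float)[1:])
        out.append(entry)
    return out


def find_accessory_canals(graph: CanalGraph, accessory_exits: set[int], third_of,
                          side=None) -> list[dict]:
    """Accessory canals: branches to sub-threshold openings, located by the
    third of their origin on the main canal.

    Exits sharing one branch origin are grouped into a single accessory canal
    carrying several accessory foramina.
    """
    by_origin: dict[int, list[int]] = {}
    for exit_id in sorted(accessory_exits):
        edges = graph.terminal_edges(exit_id)
        origin = edges[-1][1] if edges else graph.exits[exit_id].node
        by_origin.setdefault(origin, []).append(exit_id)
    out = []
    for origin, exit_ids in by_origin.items():
        pos = graph.node_pos(origin)
        entry = {
            "origin_index": [float(x) for x in pos],
            "third": third_of(float(pos[0]) * graph.voxel_size_mm),
            "n_foramina": len(exit_ids),
            "opening_diameters_mm": [
                round(graph.exits[i].opening_diameter_mm, 3) for i in exit_ids
            ],
        }
        if side is not None:
            entry["root"] = side(np.asarray(pos, dtype=float)[1:])
        out.append(entry)
    return out
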