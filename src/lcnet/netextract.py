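"""From binarized canaliculi to a spatial network.

Three stages mirror the image-to-connectome conversion: (1) topology
preserving 3D thinning of the canalicular foreground to one-voxel-wide
centre lines, (2) chain-graph construction — skeleton voxels are classified
by their 26-neighbour count into end (1), chain (2) and branch (>=3) voxels,
branch clusters collapse to junction nodes, skeleton voxels touching a
lacuna anchor their chain to that lacuna's node — and (3) third-order
parametric spline fitting per chain with arc-length measurement by adaptive
quadrature of the spline speed.

All geometry is carried in physical units (um) with anisotropic voxel sizes;
voxel (i, j, k) maps to the point ((i+0.5) s0, (j+0.5) s1, (k+0.5) s2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.interpolate import splev, splprep
from skimage.morphology import skeletonize as _sk_skeletonize

from .types import PORE_CANALICULAR, PORE_LACUNAR, BinaryVolume, LCNetwork

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                     if (dx, dy, dz) != (0, 0, 0)], dtype=int)


def skeletonize(binary: BinaryVolume | np.ndarray) -> np.ndarray:
    """Thin the canalicular foreground to 26-connected centre lines.

    Uses a 3D topology-preserving parallel thinning, so the number of
    connected components (and loops) of the input is preserved.  When the
    input volume carries pore-class labels only the canalicular class is
    thinned; lacunae enter the graph later as node anchors.
    """
    if isinstance(binary, BinaryVolume):
        if binary.class_labels is not None:
            mask = binary.class_labels == PORE_CANALICULAR
        else:
            mask = binary.foreground
    else:
        mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    skel = _sk_skeletonize(mask).astype(bool)
    # parallel thinning may erase one/two-voxel debris components outright;
    # re-seed them so the connected-component count is exactly preserved
    lbl, n = ndimage.label(mask, structure=_STRUCT26)
    if n:
        present = np.zeros(n + 1, dtype=bool)
        present[lbl[skel]] = True
        for ci in np.nonzero(~present[1:])[0] + 1:
            seed = tuple(np.argwhere(lbl == ci)[0])
            skel[seed] = True
    return skel


@dataclass
class SkeletonNode:
    kind: str                      # junction / endpoint / lacunar / loop
    position_vox: np.ndarray       # float voxel-index coordinates
    voxels: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class Chain:
    u: int
    v: int
    voxels: np.ndarray             # (m, 3) int voxel indices, ordered u -> v


@dataclass
class SkeletonGraph:
    """Intermediate chain-graph between thinning and spline fitting."""

    nodes: dict[int, SkeletonNode]
    chains: list[Chain]
    voxel_size: tuple[float, float, float]

    def degrees(self) -> dict[int, int]:
        d = {nid: 0 for nid in self.nodes}
        for c in self.chains:
            d[c.u] += 1
            d[c.v] += 1
        return d


def _chain_length_um(voxels: np.ndarray, vs: np.ndarray) -> float:
    if len(voxels) < 2:
        return 0.0
    steps = np.diff(voxels.astype(float), axis=0) * vs
    return float(np.linalg.norm(steps, axis=1).sum())


def build_chain_graph(
    skeleton: np.ndarray,
    lacunar_mask: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (0.303, 0.303, 0.27),
    merge_radius: int = 1,
    prune_length: float = 1.0,
    foreground: np.ndarray | None = None,
) -> SkeletonGraph:
    """Convert a voxel skeleton into chains between nodes.

    Skeleton voxels with one 26-neighbour terminate chains (endpoints), with
    three or more become branch voxels; branch voxels closer than
    ``merge_radius`` (Chebyshev, voxels) collapse into a single junction node
    at their centroid, since parallel thinning emits small clusters of branch
    voxels at one anatomical junction.  Skeleton voxels touching
    ``lacunar_mask`` anchor their chain to the lacuna's node (placed at the
    lacunar component centroid).  Pure cycles with no branch voxel get one
    node at their lexicographically smallest voxel and a self-edge.  Free
    ending chains shorter than ``prune_length`` um are pruned as thinning
    artefacts.  When the original ``foreground`` is supplied, free chain ends
    are extended along their local tangent through foreground voxels the
    thinning retracted (tube caps), recovering the length bias of
    skeletonization at canaliculus tips.
    """
    vs = np.asarray(voxel_size, dtype=float)
    skeleton = np.asarray(skeleton, dtype=bool)
    coords = sorted(map(tuple, np.argwhere(skeleton)))
    nodes: dict[int, SkeletonNode] = {}
    chains: list[Chain] = []
    if not coords:
        return SkeletonGraph(nodes, chains, tuple(vs))

    nbr_count = ndimage.convolve(skeleton.astype(np.uint8),
                                 _STRUCT26.astype(np.uint8),
                                 mode="constant") - 1
    skel_set = set(coords)

    branch_mask = skeleton & (nbr_count >= 3)
    # merge nearby branch voxels: label the dilated mask, read labels back
    if merge_radius > 1:
        grown = ndimage.binary_dilation(branch_mask, structure=_STRUCT26,
                                        iterations=merge_radius - 1)
    else:
        grown = branch_mask
    cluster_lbl, _n = ndimage.label(grown, structure=_STRUCT26)

    next_id = 0
    voxel_node: dict[tuple[int, int, int], int] = {}

    for cl in np.unique(cluster_lbl[branch_mask]):
        members = sorted(map(tuple, np.argwhere(branch_mask & (cluster_lbl == cl))))
        nid = next_id
        next_id += 1
        pos = np.mean(np.asarray(members, dtype=float), axis=0)
        nodes[nid] = SkeletonNode("junction", pos, members)
        for m in members:
            voxel_node[m] = nid

    if lacunar_mask is not None and np.asarray(lacunar_mask).any():
        lac_lbl, _n_lac = ndimage.label(np.asarray(lacunar_mask, bool),
                                        structure=_STRUCT26)
        # contact search reaches 2 voxels out: thinning retracts chain ends
        # slightly from the lacunar surface
        near = ndimage.grey_dilation(lac_lbl, size=(5, 5, 5))
        touch = (near > 0) & skeleton
        lac_nodes: dict[int, int] = {}
        for c in sorted(map(tuple, np.argwhere(touch))):
            if c in voxel_node:      # branch voxels keep junction precedence
                continue
            lid = int(near[c])
            if lid not in lac_nodes:
                nid = next_id
                next_id += 1
                centroid = np.asarray(ndimage.center_of_mass(lac_lbl == lid))
                nodes[nid] = SkeletonNode("lacunar", centroid, [])
                lac_nodes[lid] = nid
            voxel_node[c] = lac_nodes[lid]

    for c in coords:
        if c not in voxel_node and nbr_count[c] == 1:
            nid = next_id
            next_id += 1
            nodes[nid] = SkeletonNode("endpoint", np.asarray(c, dtype=float), [c])
            voxel_node[c] = nid

    def neighbours(c: tuple[int, int, int]):
        for off in _OFFSETS:
            p = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if p in skel_set:
                yield p

    # --- trace chains between terminal voxels --------------------------------
    visited: set[tuple[int, int, int]] = set()
    seen_pairs: set[tuple] = set()
    for t in sorted(voxel_node):
        t_node = voxel_node[t]
        for n in neighbours(t):
            if n in voxel_node:
                if voxel_node[n] == t_node:
                    continue  # intra-cluster / same-lacuna adjacency
                key = (min(t, n), max(t, n))
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                chains.append(Chain(t_node, voxel_node[n], np.asarray([t, n])))
            else:
                if n in visited:
                    continue
                path = [t, n]
                visited.add(n)
                prev, cur = t, n
                while cur not in voxel_node:
                    nxt = None
                    for m in neighbours(cur):
                        if m != prev:
                            nxt = m
                            break
                    if nxt is None:
                        break
                    path.append(nxt)
                    if nxt not in voxel_node:
                        visited.add(nxt)
                    prev, cur = cur, nxt
                if cur in voxel_node:
                    chains.append(Chain(t_node, voxel_node[cur], np.asarray(path)))

    # --- pure cycles: components made only of degree-2 voxels ----------------
    leftover_set = {c for c in skel_set
                    if c not in visited and c not in voxel_node
                    and nbr_count[c] == 2}
    for c0 in sorted(leftover_set):
        if c0 not in leftover_set:
            continue
        nid = next_id
        next_id += 1
        nodes[nid] = SkeletonNode("loop", np.asarray(c0, dtype=float), [c0])
        path = [c0]
        leftover_set.discard(c0)
        prev, cur = None, c0
        while True:
            nxt = None
            for m in neighbours(cur):
                if m != prev and (m in leftover_set or (m == c0 and len(path) > 2)):
                    nxt = m
                    break
            if nxt is None:
                break
            path.append(nxt)
            if nxt == c0:
                break
            leftover_set.discard(nxt)
            prev, cur = cur, nxt
        if len(path) > 2 and path[-1] == c0:
            chains.append(Chain(nid, nid, np.asarray(path)))

    graph = SkeletonGraph(nodes, chains, tuple(vs))
    if foreground is not None:
        _extend_free_ends(graph, np.asarray(foreground, bool), skel_set, vs)
    _prune_and_simplify(graph, vs, prune_length)
    return graph


def _extend_free_ends(graph: SkeletonGraph, foreground: np.ndarray,
                      skel_set: set, vs: np.ndarray, max_ext: int = 8) -> None:
    """Grow endpoint chains along their tangent through retracted foreground.

    Thinning retracts a tube's centre line by about one radius from each cap.
    The retracted stretch is recovered by walking outward through foreground
    voxels whose clearance (distance to background) matches the local tube
    radius — the walk stops where the clearance drops, i.e. inside the cap
    beyond the true axis endpoint.
    """
    shape = foreground.shape
    occupied = set(skel_set)
    edt = ndimage.distance_transform_edt(foreground, sampling=vs)
    for chain in graph.chains:
        for end, ordered in ((chain.u, chain.voxels[::-1]), (chain.v, chain.voxels)):
            node = graph.nodes[end]
            if node.kind != "endpoint" or len(ordered) < 2:
                continue
            tail = ordered[-min(5, len(ordered)):].astype(float)
            direction = (tail[-1] - tail[0]) * vs
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            direction /= norm
            cur = tuple(int(x) for x in ordered[-1])
            clearance = edt[cur] - 0.51 * float(vs.min())
            added = []
            for _ in range(max_ext):
                best = None
                best_cos = 0.5
                for off in _OFFSETS:
                    cand = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                    if not all(0 <= cand[ax] < shape[ax] for ax in range(3)):
                        continue
                    if cand in occupied or not foreground[cand]:
                        continue
                    if edt[cand] < clearance:
                        continue  # narrowing: we are past the axis endpoint
                    step = off * vs
                    cos = float(np.dot(step, direction) / np.linalg.norm(step))
                    if cos > best_cos:
                        best_cos = cos
                        best = cand
                if best is None:
                    break
                added.append(best)
                occupied.add(best)
                cur = best
            if added:
                ext = np.asarray(added, dtype=int)
                if end == chain.v:
                    chain.voxels = np.concatenate([chain.voxels, ext])
                else:
                    chain.voxels = np.concatenate([ext[::-1], chain.voxels])
                node.position_vox = np.asarray(added[-1], dtype=float)
                node.voxels = [added[-1]]


def _prune_and_simplify(graph: SkeletonGraph, vs: np.ndarray,
                        prune_length: float) -> None:
    """Drop short free-ending spurs, then splice pass-through junctions."""
    for _round in range(5):
        changed = False
        degrees = graph.degrees()

        kept: list[Chain] = []
        for c in graph.chains:
            free_end = any(
                graph.nodes[end].kind == "endpoint" and degrees[end] == 1
                for end in (c.u, c.v))
            if free_end and _chain_length_um(c.voxels, vs) < prune_length:
                changed = True
            else:
                kept.append(c)
        graph.chains = kept
        degrees = graph.degrees()

        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            if node.kind != "junction" or degrees.get(nid, 0) != 2:
                continue
            incident = [c for c in graph.chains if nid in (c.u, c.v)]
            if len(incident) != 2:   # a degree-2 self-loop stays as is
                continue
            a, b = incident
            pa = a.voxels if a.v == nid else a.voxels[::-1]
            pb = b.voxels if b.u == nid else b.voxels[::-1]
            new_u = a.u if a.v == nid else a.v
            new_v = b.v if b.u == nid else b.u
            merged = np.concatenate([pa, pb[1:]]) if tuple(pa[-1]) == tuple(pb[0]) \
                else np.concatenate([pa, pb])
            graph.chains.remove(a)
            graph.chains.remove(b)
            graph.chains.append(Chain(new_u, new_v, merged))
            del graph.nodes[nid]
            changed = True
            degrees = graph.degrees()

        for nid in sorted(graph.nodes):
            d = degrees.get(nid, 0)
            node = graph.nodes[nid]
            if d == 0 and node.kind != "lacunar":
                del graph.nodes[nid]
                changed = True
            elif node.kind == "junction" and d == 1:
                node.kind = "endpoint"
                changed = True
        if not changed:
            break


# ---------------------------------------------------------------------------
# spline fitting


def _spline_arc_length(tck) -> float:
    def speed(t: float) -> float:
        dx, dy, dz = splev(t, tck, der=1)
        return float(np.sqrt(dx * dx + dy * dy + dz * dz))

    val, _err = quad(speed, 0.0, 1.0, epsabs=1e-9, epsrel=1e-9, limit=200)
    return float(val)


def fit_splines(
    graph: SkeletonGraph,
    smoothing: float = 0.2,
    sample_step: float = 0.2,
) -> LCNetwork:
    """Fit order-3 parametric splines to every chain and build the network.

    Each chain's voxel centres (um) are fitted by a smoothing spline over the
    cumulative chordal parameter (``smoothing`` is the allowed RMS residual
    in um, tight enough that every chain voxel stays within half a voxel
    diagonal of the curve).  Junction chains are extended to the junction
    centroid so edge endpoints coincide with node positions; chains anchored
    to a lacuna keep their geometric end at the lacunar surface — only the
    topology attaches to the lacuna node.  Arc length (Can.Ln) is computed by
    adaptive quadrature of the spline speed.
    """
    vs = np.asarray(graph.voxel_size, dtype=float)
    net = LCNetwork()
    for nid, node in graph.nodes.items():
        net.add_node(nid, (node.position_vox + 0.5) * vs, node.kind)

    for chain in graph.chains:
        pts = (chain.voxels.astype(float) + 0.5) * vs
        for endn, where in ((chain.u, "start"), (chain.v, "end")):
            node = graph.nodes[endn]
            if node.kind in ("junction", "loop"):
                p_node = (node.position_vox + 0.5) * vs
                if where == "start" and not np.allclose(p_node, pts[0]):
                    pts = np.vstack([p_node, pts])
                elif where == "end" and not np.allclose(p_node, pts[-1]):
                    pts = np.vstack([pts, p_node])
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        pts = pts[keep]
        if len(pts) < 2:
            continue  # degenerate chain folds into its node

        chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(chord)])
        u /= u[-1]
        k = min(3, len(pts) - 1)
        s = len(pts) * smoothing ** 2
        try:
            tck, _u = splprep(list(pts.T), u=u, k=k, s=s)
        except (ValueError, TypeError):
            tck, _u = splprep(list(pts.T), u=u, k=1, s=0)
        arc = _spline_arc_length(tck)
        n_samp = max(int(np.ceil(arc / sample_step)) + 1, 9)
        t = np.linspace(0.0, 1.0, n_samp)
        poly = np.column_stack(splev(t, tck))
        net.add_edge(chain.u, chain.v, poly, arc_length=arc, tck=tck)

    return net


def extract_network(
    binary: BinaryVolume,
    merge_radius: int = 1,
    prune_length: float = 1.0,
    smoothing: float = 0.2,
) -> LCNetwork:
    """Full image-to-network conversion: thinning, chain graph, splines."""
    skel = skeletonize(binary)
    lac = None
    fg = binary.foreground
    if binary.class_labels is not None:
        lac = binary.class_labels == PORE_LACUNAR
        fg = binary.class_labels == PORE_CANALICULAR
    graph = build_chain_graph(skel, lacunar_mask=lac,
                              voxel_size=binary.voxel_size,
                              merge_radius=merge_radius,
                              prune_length=prune_length,
                              foreground=fg)
    return fit_splines(graph, smoothing=smoothing)
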