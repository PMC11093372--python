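"""Synthetic lacuno-canalicular phantoms with known ground truth.

Real LCN image data is rarely shareable, so every downstream stage of the
pipeline is validated against phantoms generated here.  The generator builds
a ground-truth spatial network first — ellipsoidal lacunae seeding biased
random-walk canaliculi that branch as a Poisson process along their length,
producing the tree-dominated graphs observed in murine cortical bone — and
then renders it into a confocal-like image stack (tube/ellipsoid
rasterization, optional PSF blur, depth attenuation and photon noise).

The growth model is deliberately minimal: it has exactly the two structural
knobs the connectomic analysis probes (edge-length distribution and branching
density), plus a density controller that fills the domain with whole
canalicular trees until a target Can.Dn is met.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import (
    PORE_CANALICULAR,
    PORE_LACUNAR,
    REGION_ENDOSTEAL_NEW,
    REGION_INTERCORTEX,
    REGION_PERIOSTEAL_NEW,
    ImageVolume,
    LCNetwork,
    RegionMask,
    resample_polyline,
)

# hard ceiling on rendered grids (number of voxels); ~0.5 GiB of float32
DEFAULT_VOXEL_BUDGET = 134_000_000

_WALK_STEP_UM = 0.25  # step of the growth random walk


@dataclass
class SyntheticSpec:
    """Parameters of the ground-truth network generator.

    Lengths in um.  Defaults describe a 50 x 50 x 30 um cortical sub-volume:
    lacunae of ~150 um^3 (murine lacunae span roughly 100-250 um^3),
    canaliculi a few um long with tree-like (degree 3) branching.
    """

    domain_size: tuple[float, float, float] = (50.0, 50.0, 30.0)
    lacuna_count: int = 6
    lacuna_semiaxes: tuple[float, float, float] = (6.0, 3.0, 2.0)
    processes_per_lacuna: int = 40
    branch_rate: float = 1.4            # branch events per um of canaliculus
    branch_refractory: float = 1.6      # um after a branch before the next
    segment_length_mean: float = 8.0    # um between nodes
    segment_length_sd: float = 4.0
    tortuosity: float = 0.08            # rad of direction noise per step
    canalicular_radius: float = 0.3     # um (unresolvable optically; free knob)
    min_separation: float = 1.0         # um steric clearance between tubes
    target_density: float | None = None  # um/um^3, or None for "unset"
    density_gradient: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.domain_size):
            raise ValueError("domain_size must be strictly positive")
        if self.lacuna_count < 0 or self.processes_per_lacuna < 0:
            raise ValueError("counts must be non-negative")
        if any(a <= 0 for a in self.lacuna_semiaxes):
            raise ValueError("lacuna semiaxes must be positive")
        if self.branch_rate < 0:
            raise ValueError("branch_rate must be >= 0")
        if self.segment_length_mean <= 0 or self.segment_length_sd < 0:
            raise ValueError("segment length parameters invalid")
        if self.canalicular_radius <= 0:
            raise ValueError("canalicular_radius must be positive")
        if self.target_density is not None and self.target_density <= 0:
            raise ValueError("target_density, if set, must be > 0")


@dataclass
class ImagingSpec:
    """Confocal acquisition emulation parameters.

    The default voxel size matches a 100x objective (303 nm in-plane) with
    ~110 optical slices over a 30 um depth (0.27 um z spacing).
    ``attenuation_per_um`` is the fractional intensity loss per um of depth.
    """

    voxel_size: tuple[float, float, float] = (0.303, 0.303, 0.27)
    psf_sigma: tuple[float, float, float] = (0.15, 0.15, 0.45)
    noise_model: str = "poisson+gaussian"
    photons_per_unit: float = 50.0
    gaussian_sd: float = 2.0
    attenuation_per_um: float = 0.0
    background_level: float = 10.0
    foreground_level: float = 100.0
    voxel_budget: int = DEFAULT_VOXEL_BUDGET

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not (0.0 <= self.attenuation_per_um < 1.0):
            raise ValueError("attenuation_per_um must lie in [0, 1)")
        if self.noise_model not in ("none", "gaussian", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    network: LCNetwork
    total_length: float
    per_cell_lengths: dict[tuple[int, int, int], float]
    lacunae: list[tuple[np.ndarray, np.ndarray]]  # (centre, semiaxes) um
    domain_size: tuple[float, float, float]
    pore_mask: np.ndarray | None = None
    seed_streams: dict[str, int] = field(default_factory=dict)


class EmptyNetworkError(ValueError):
    pass


class InfeasibleDensityError(ValueError):
    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"cannot reach target density {target:g} um/um^3; "
            f"achieved {achieved:g} um/um^3"
        )


# ---------------------------------------------------------------------------
# growth model


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perturb(direction: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a random small angle of scale ``amplitude``."""
    if amplitude <= 0:
        return direction
    noise = rng.normal(scale=amplitude, size=3)
    return _unit(direction + np.cross(noise, direction))


def _branch_directions(direction: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two daughter directions at a branch point, splayed around the parent."""
    angle = rng.normal(0.6, 0.15)  # ~35 deg half-angle
    perp = _unit(np.cross(direction, _random_unit(rng)))
    d1 = _unit(np.cos(angle) * direction + np.sin(angle) * perp)
    d2 = _unit(np.cos(angle) * direction - np.sin(angle) * perp)
    return d1, d2


class _CollisionGrid:
    """Spatial hash of laid-down tube samples for steric avoidance.

    Canaliculi are distinct channels that must stay resolvable in the
    rendered image, so a growing walker may not come within ``min_sep`` of
    any previously laid tube — not even its own tree's other branches.  The
    only exemptions are the walker's own trailing samples (within
    ``tail_arc`` of its current arc position) and samples near its birth
    point (its parent edge and sibling's first steps at the shared branch).
    """

    def __init__(self, min_sep: float, tail_arc: float = 2.5,
                 birth_radius: float = 1.5):
        self.min_sep = float(min_sep)
        self.tail_arc = float(tail_arc)
        self.birth_radius2 = float(birth_radius) ** 2
        self.cell = max(self.min_sep, 1e-6)
        self.table: dict[tuple[int, int, int], list] = {}

    def add(self, p: np.ndarray, tree_id: int, walker_id: int, arc: float) -> None:
        c = self.cell
        key = (int(p[0] // c), int(p[1] // c), int(p[2] // c))
        self.table.setdefault(key, []).append(
            (float(p[0]), float(p[1]), float(p[2]), tree_id, walker_id,
             float(arc)))

    def nearest_obstacle(self, p: np.ndarray, tree_id: int = -1,
                         walker_id: int = -1, arc: float = 0.0,
                         birth: np.ndarray | None = None) -> np.ndarray | None:
        """Closest non-exempt sample within min_sep of p, or None."""
        c = self.cell
        p0, p1, p2 = float(p[0]), float(p[1]), float(p[2])
        k0, k1, k2 = int(p0 // c), int(p1 // c), int(p2 // c)
        b0, b1, b2 = (float(birth[0]), float(birth[1]), float(birth[2])) \
            if birth is not None else (np.inf, np.inf, np.inf)
        best = None
        best_d2 = self.min_sep ** 2
        get = self.table.get
        for a in (k0 - 1, k0, k0 + 1):
            for b in (k1 - 1, k1, k1 + 1):
                for cc in (k2 - 1, k2, k2 + 1):
                    bucket = get((a, b, cc))
                    if not bucket:
                        continue
                    for q0, q1, q2, t2, w2, arc2 in bucket:
                        if t2 == tree_id:
                            if w2 == walker_id and arc - arc2 < self.tail_arc:
                                continue  # my own trailing samples
                            bd2 = (q0 - b0) ** 2 + (q1 - b1) ** 2 + (q2 - b2) ** 2
                            if bd2 < self.birth_radius2:
                                continue  # parent edge / sibling at my branch
                        d2 = (p0 - q0) ** 2 + (p1 - q1) ** 2 + (p2 - q2) ** 2
                        if d2 < best_d2:
                            best_d2 = d2
                            best = (q0, q1, q2)
        return None if best is None else np.asarray(best)


def _segment_budget(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    # clipped below at 2 um: segments shorter than the imaging resolution
    # would make the phantom unverifiable, not more realistic
    return max(float(rng.normal(spec.segment_length_mean, spec.segment_length_sd)),
               min(2.0, spec.segment_length_mean))


def _local_density_factor(spec: SyntheticSpec, p: np.ndarray) -> float:
    """Linear density modulation across the domain, normalized to mean 1."""
    if spec.density_gradient is None:
        return 1.0
    g = np.asarray(spec.density_gradient, dtype=float)
    centre = np.asarray(spec.domain_size) / 2.0
    return max(0.0, 1.0 + float(np.dot(g, p - centre)))


def _grow_tree(
    net: LCNetwork,
    root_node: int,
    start: np.ndarray,
    direction: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    grid: _CollisionGrid | None = None,
    tree_id: int = 0,
    max_edges: int = 200,
) -> float:
    """Grow one canalicular tree from a lacunar surface point.

    Returns the total arc length added.  Each walker lays down a polyline
    until its segment-length budget runs out (endpoint node), a Poisson
    branch event fires (junction node, two daughters), it hits the domain
    boundary (clipped endpoint), or it comes within the steric clearance of
    another tree (terminated; canaliculi do not fuse).
    """
    domain = np.asarray(spec.domain_size)
    total = 0.0
    n_edges = 0
    walker_seq = [0]
    # stack of walkers: (anchor node, position, direction, walker id,
    #                    cumulative arc at spawn, birth position)
    stack = [(root_node, start.copy(), direction.copy(), walker_seq[0], 0.0,
              start.copy())]
    while stack:
        parent, pos, d, walker_id, arc0, birth = stack.pop()
        budget = _segment_budget(spec, rng)
        to_branch = (spec.branch_refractory + rng.exponential(1.0 / spec.branch_rate)
                     if spec.branch_rate > 0 else np.inf)
        path = [pos.copy()]
        travelled = 0.0
        terminal = "endpoint"
        while True:
            step = min(_WALK_STEP_UM, budget, to_branch)
            d = _perturb(d, spec.tortuosity, rng)
            nxt = pos + step * d
            if np.any(nxt < 0) or np.any(nxt > domain):
                # clip the final step to the boundary and stop
                t_hit = 1.0
                for ax in range(3):
                    if d[ax] > 0 and nxt[ax] > domain[ax]:
                        t_hit = min(t_hit, (domain[ax] - pos[ax]) / (step * d[ax]))
                    elif d[ax] < 0 and nxt[ax] < 0:
                        t_hit = min(t_hit, (0.0 - pos[ax]) / (step * d[ax]))
                t_hit = max(t_hit, 0.0)
                nxt = pos + step * t_hit * d
                path.append(nxt.copy())
                terminal = "endpoint"
                break
            if grid is not None:
                # steric response: slide along a nearby tube (remove the
                # approaching velocity component, add a small outward bias)
                # the way processes fasciculate; give up when trapped
                blocked = False
                arc_now = arc0 + travelled + step
                for _attempt in range(4):
                    obstacle = grid.nearest_obstacle(nxt, tree_id, walker_id,
                                                     arc_now, birth)
                    if obstacle is None:
                        break
                    n_hat = nxt - obstacle
                    norm = np.linalg.norm(n_hat)
                    n_hat = n_hat / norm if norm > 0 else _random_unit(rng)
                    approach = float(np.dot(d, n_hat))
                    if approach < 0:
                        d = d - approach * n_hat
                    d = _unit(d + 0.3 * n_hat)
                    nxt = pos + step * d
                else:
                    blocked = True
                if blocked:
                    terminal = "endpoint"
                    break
                if np.any(nxt < 0) or np.any(nxt > domain):
                    terminal = "endpoint"
                    break
            pos = nxt
            travelled += step
            path.append(pos.copy())
            if grid is not None:
                grid.add(pos, tree_id, walker_id, arc0 + travelled)
            budget -= step
            to_branch -= step
            if to_branch <= 1e-12:
                # only branch if both daughters have room to get started;
                # otherwise keep running and re-arm the branch clock
                branch_dirs = _branch_directions(d, rng)
                probes = [pos + probe * dd for dd in branch_dirs
                          for probe in (0.9, 1.7, 2.5)]
                room = all(np.all(q >= 0) and np.all(q <= domain) for q in probes)
                if room and spec.density_gradient is not None:
                    # gradient phantoms branch preferentially where the
                    # prescribed density is high
                    room = rng.uniform() < _local_density_factor(spec, pos)
                if room and grid is not None:
                    room = all(grid.nearest_obstacle(q, tree_id, birth=pos)
                               is None for q in probes)
                if room:
                    terminal = "junction"
                    break
                to_branch = spec.branch_refractory + \
                    rng.exponential(1.0 / spec.branch_rate)
            if budget <= 1e-12:
                terminal = "endpoint"
                break
        poly = np.asarray(path)
        if len(poly) < 2:
            continue
        arc = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        if arc <= 0:
            continue
        node_id = net.new_node_id()
        if terminal == "junction" and n_edges < max_edges:
            net.add_node(node_id, poly[-1], "junction")
            end_arc = arc0 + travelled
            for dd in branch_dirs:
                walker_seq[0] += 1
                stack.append((node_id, poly[-1].copy(), dd, walker_seq[0],
                              end_arc, poly[-1].copy()))
        else:
            net.add_node(node_id, poly[-1], "endpoint")
        net.add_edge(parent, node_id, poly, arc_length=arc)
        total += arc
        n_edges += 1
    return total


def _place_lacunae(spec: SyntheticSpec, rng: np.random.Generator
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    domain = np.asarray(spec.domain_size)
    semi = np.asarray(spec.lacuna_semiaxes, dtype=float)
    lo = np.minimum(semi, domain / 2.0)
    hi = np.maximum(domain - semi, domain / 2.0)
    lacunae: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.lacuna_count):
        centre = None
        for _attempt in range(50):  # rejection sampling against overlap
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm((c - c2) / (semi + s2)) >= 1.0 for c2, s2 in lacunae):
                centre = c
                break
        if centre is None:
            centre = rng.uniform(lo, hi)  # accept overlap after many tries
        lacunae.append((centre, semi.copy()))
    return lacunae


def _ellipsoid_surface_point(centre: np.ndarray, semi: np.ndarray,
                             direction: np.ndarray) -> np.ndarray:
    scale = 1.0 / np.sqrt(np.sum((direction / semi) ** 2))
    return centre + scale * direction


def generate_network(spec: SyntheticSpec) -> tuple[LCNetwork, GroundTruth]:
    """Build the ground-truth LCN graph for ``spec``.

    Lacunae become "lacunar" nodes at their centroids; canalicular trees grow
    from points on each lacunar surface.  When ``target_density`` is set,
    whole trees are added round-robin over the lacunae until the total edge
    length reaches ``target_density x domain volume`` (within 5%); otherwise
    exactly ``processes_per_lacuna`` trees grow per lacuna.
    """
    if spec.lacuna_count == 0 and spec.processes_per_lacuna == 0:
        raise EmptyNetworkError("zero lacunae with zero processes yields an empty network")
    ss = np.random.SeedSequence(spec.seed)
    child_place, child_grow = ss.spawn(2)
    rng_place = np.random.default_rng(child_place)
    rng_grow = np.random.default_rng(child_grow)

    net = LCNetwork()
    lacunae = _place_lacunae(spec, rng_place)
    lacuna_nodes = []
    for centre, _semi in lacunae:
        nid = net.new_node_id()
        net.add_node(nid, centre, "lacunar")
        lacuna_nodes.append(nid)

    domain_volume = float(np.prod(spec.domain_size))
    total = 0.0
    grid = _CollisionGrid(spec.min_separation) if spec.min_separation > 0 else None
    tree_counter = [0]

    def sprout(lacuna_idx: int) -> float:
        centre, semi = lacunae[lacuna_idx]
        d = _random_unit(rng_grow)
        start = _ellipsoid_surface_point(centre, semi, d)
        if spec.density_gradient is not None:
            # thin sprouts in sparse regions so realized length tracks the gradient
            if rng_grow.uniform() > _local_density_factor(spec, start):
                return 0.0
        start = np.clip(start, 0.0, np.asarray(spec.domain_size))
        tree_counter[0] += 1
        if grid is not None and \
                grid.nearest_obstacle(start, tree_counter[0]) is not None:
            return 0.0  # surface site already occupied: no room to sprout
        return _grow_tree(net, lacuna_nodes[lacuna_idx], start, d, spec,
                          rng_grow, grid=grid, tree_id=tree_counter[0])

    if spec.target_density is None:
        if not lacuna_nodes:
            raise EmptyNetworkError("no lacunae to sprout processes from")
        for li in range(len(lacunae)):
            for _p in range(spec.processes_per_lacuna):
                total += sprout(li)
    else:
        target_length = spec.target_density * domain_volume
        max_trees = max(200, 60 * spec.lacuna_count * max(spec.processes_per_lacuna, 1))
        n_trees = 0
        li = 0
        barren = 0  # consecutive sprouts adding (almost) nothing: saturation
        if not lacuna_nodes:
            raise EmptyNetworkError("no lacunae to sprout processes from")
        while total < target_length and n_trees < max_trees:
            added = sprout(li)
            barren = barren + 1 if added < 0.5 else 0
            total += added
            li = (li + 1) % len(lacunae)
            n_trees += 1
            if barren > max(600, 100 * len(lacunae)):
                break  # the domain is sterically saturated
        if total < target_length * 0.95:
            raise InfeasibleDensityError(spec.target_density, total / domain_volume)

    gt = GroundTruth(
        network=net,
        total_length=net.total_length,
        per_cell_lengths=true_cell_lengths(net, spec.domain_size, edge_length=5.0),
        lacunae=lacunae,
        domain_size=spec.domain_size,
        seed_streams={"placement": int(child_place.generate_state(1)[0] % 2**31),
                      "growth": int(child_grow.generate_state(1)[0] % 2**31)},
    )
    return net, gt


def true_cell_lengths(network: LCNetwork, domain_size, edge_length: float = 5.0,
                      sample_step: float = 0.05) -> dict[tuple[int, int, int], float]:
    """Exact-by-construction canalicular length per cubic sub-volume.

    Edges are resampled at ``sample_step`` um and each length increment is
    assigned to the cell holding its midpoint (half-open cells; samples on
    the outer domain face fold into the last cell so length is conserved).
    """
    domain = np.asarray(domain_size, dtype=float)
    shape = np.maximum(np.ceil(domain / edge_length - 1e-9).astype(int), 1)
    acc: dict[tuple[int, int, int], float] = {}
    for *_uvk, geom in network.edges():
        mids, seglens = resample_polyline(geom.polyline, sample_step)
        if len(seglens) == 0:
            continue
        inside = np.all((mids >= 0) & (mids <= domain), axis=1)
        idx = np.floor(mids[inside] / edge_length).astype(int)
        idx = np.minimum(idx, shape - 1)
        for cell, ln in zip(map(tuple, idx), seglens[inside]):
            acc[cell] = acc.get(cell, 0.0) + float(ln)
    return acc


# ---------------------------------------------------------------------------
# rendering


def _grid_shape(domain_size, voxel_size) -> np.ndarray:
    return np.maximum(np.round(np.asarray(domain_size, float) /
                               np.asarray(voxel_size, float)).astype(int), 1)


def render_volume(
    network: LCNetwork,
    ground_truth: GroundTruth,
    imaging: ImagingSpec,
    canalicular_radius: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[ImageVolume, np.ndarray]:
    """Rasterize the network into a rhodamine-like stack.

    Returns the rendered :class:`ImageVolume` and the noise-free ground-truth
    pore mask (0 background, 1 canalicular, 2 lacunar) taken *before* PSF
    blur, attenuation and noise.  Membership is exact: a voxel is canalicular
    foreground iff its centre lies within ``canalicular_radius`` of an edge
    polyline, lacunar iff its centre lies inside a lacunar ellipsoid.
    """
    domain = np.asarray(ground_truth.domain_size, dtype=float)
    vs = np.asarray(imaging.voxel_size, dtype=float)
    shape = _grid_shape(domain, vs)
    if int(np.prod(shape)) > imaging.voxel_budget:
        raise MemoryError(
            f"rendering grid {tuple(shape)} exceeds the voxel budget "
            f"({int(np.prod(shape))} > {imaging.voxel_budget}); coarsen "
            f"voxel_size or shrink the domain"
        )
    radius = float(canalicular_radius) if canalicular_radius is not None else 0.3
    mask = np.zeros(tuple(shape), dtype=np.uint8)

    for *_uvk, geom in network.edges():
        _rasterize_tube(mask, geom.polyline, radius, vs, PORE_CANALICULAR)
    for centre, semi in ground_truth.lacunae:
        _rasterize_ellipsoid(mask, centre, semi, vs, PORE_LACUNAR)

    img = np.full(tuple(shape), float(imaging.background_level), dtype=np.float64)
    img[mask > 0] = imaging.foreground_level

    if any(s > 0 for s in imaging.psf_sigma):
        sigma_vox = np.asarray(imaging.psf_sigma, float) / vs
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if imaging.attenuation_per_um > 0:
        depth = (np.arange(shape[2]) + 0.5) * vs[2]
        img *= (1.0 - imaging.attenuation_per_um) ** depth[None, None, :]
    img = _apply_noise(img, imaging, rng)

    volume = ImageVolume(img, tuple(vs), channel="rhodamine")
    ground_truth.pore_mask = mask
    return volume, mask


def _apply_noise(img: np.ndarray, imaging: ImagingSpec,
                 rng: np.random.Generator | int | None) -> np.ndarray:
    if imaging.noise_model == "none":
        return img
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = img
    if "poisson" in imaging.noise_model:
        lam = np.clip(out, 0, None) * imaging.photons_per_unit
        out = rng.poisson(lam).astype(np.float64) / imaging.photons_per_unit
    if "gaussian" in imaging.noise_model:
        out = out + rng.normal(0.0, imaging.gaussian_sd, size=out.shape)
    return out


def _voxel_range(lo: np.ndarray, hi: np.ndarray, vs: np.ndarray,
                 shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray] | None:
    i0 = np.maximum(np.floor(lo / vs - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / vs + 0.5).astype(int) + 1, np.asarray(shape))
    if np.any(i0 >= i1):
        return None
    return i0, i1


def _rasterize_tube(mask: np.ndarray, poly: np.ndarray, radius: float,
                    vs: np.ndarray, label: int) -> None:
    if len(poly) < 2:
        return
    pad = radius + 1e-9
    rng_idx = _voxel_range(poly.min(axis=0) - pad, poly.max(axis=0) + pad, vs, mask.shape)
    if rng_idx is None:
        return
    i0, i1 = rng_idx
    ax = [np.arange(i0[k], i1[k]) for k in range(3)]
    centres = np.stack(np.meshgrid(*[(a + 0.5) * vs[k] for k, a in enumerate(ax)],
                                   indexing="ij"), axis=-1)
    pts = centres.reshape(-1, 3)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ab2 = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-30)
    dmin = np.full(len(pts), np.inf)
    # chunk over segments to bound memory for long edges
    for s0 in range(0, len(a), 64):
        s1 = min(s0 + 64, len(a))
        ap = pts[:, None, :] - a[None, s0:s1, :]
        t = np.clip(np.einsum("psk,sk->ps", ap, ab[s0:s1]) / ab2[None, s0:s1], 0.0, 1.0)
        proj = a[None, s0:s1, :] + t[..., None] * ab[None, s0:s1, :]
        d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
        dmin = np.minimum(dmin, d.min(axis=1))
    hit = (dmin <= radius).reshape(centres.shape[:3])
    sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub[hit & (sub == 0)] = label


def _rasterize_ellipsoid(mask: np.ndarray, centre: np.ndarray, semi: np.ndarray,
                         vs: np.ndarray, label: int) -> None:
    rng_idx = _voxel_range(centre - semi, centre + semi, vs, mask.shape)
    if rng_idx is None:
        return
    i0, i1 = rng_idx
    ax = [(np.arange(i0[k], i1[k]) + 0.5) * vs[k] for k in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    inside = (((xx - centre[0]) / semi[0]) ** 2 +
              ((yy - centre[1]) / semi[1]) ** 2 +
              ((zz - centre[2]) / semi[2]) ** 2) <= 1.0
    mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]][inside] = label


# ---------------------------------------------------------------------------
# calcein label surfaces


@dataclass
class SurfaceSpec:
    """One calcein label surface crossing the cortex.

    ``kind`` is "planar" or "sinusoidal".  The surface gives the transcortical
    coordinate as a function of the longitudinal coordinate:
    ``x(y) = position + amplitude * sin(2*pi*y / period)``.
    """

    position: float
    kind: str = "planar"
    amplitude: float = 0.0
    period: float = 25.0

    def evaluate(self, longitudinal: np.ndarray) -> np.ndarray:
        if self.kind == "planar":
            return np.full_like(longitudinal, self.position, dtype=float)
        if self.kind == "sinusoidal":
            return self.position + self.amplitude * np.sin(
                2.0 * np.pi * longitudinal / self.period)
        raise ValueError(f"unknown surface kind {self.kind!r}")


def generate_calcein_surfaces(
    domain_size,
    surface_spec: tuple[SurfaceSpec, SurfaceSpec],
    voxel_size=(0.303, 0.303, 0.27),
    band_half_width: float = 0.45,
    transcortical_axis: int = 1,
    endosteal_low: bool = True,
) -> tuple[ImageVolume, RegionMask]:
    """Render the two calcein label bands and the anatomical region partition.

    The two surfaces must be ordered along the transcortical axis and must not
    intersect.  Every voxel receives exactly one region label: below the first
    surface is newly formed bone at the low face, between the surfaces the
    intercortex, beyond the second surface newly formed bone at the high face
    (which face is endosteal is set by ``endosteal_low``).
    """
    s1, s2 = surface_spec
    domain = np.asarray(domain_size, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    shape = _grid_shape(domain, vs)
    if transcortical_axis != 1:
        raise NotImplementedError("only transcortical axis 1 is supported")

    ylong = (np.arange(shape[0]) + 0.5) * vs[0]
    b1 = s1.evaluate(ylong)
    b2 = s2.evaluate(ylong)
    if np.any(b1 >= b2):
        raise ValueError("calcein surfaces intersect or are out of order")

    x = (np.arange(shape[1]) + 0.5) * vs[1]
    xx = x[None, :]  # (1, nx)
    low = xx < b1[:, None]
    high = xx >= b2[:, None]

    labels2d = np.full((shape[0], shape[1]),
                       REGION_INTERCORTEX, dtype=np.uint8)
    low_label = REGION_ENDOSTEAL_NEW if endosteal_low else REGION_PERIOSTEAL_NEW
    high_label = REGION_PERIOSTEAL_NEW if endosteal_low else REGION_ENDOSTEAL_NEW
    labels2d[low] = low_label
    labels2d[high] = high_label
    labels = np.repeat(labels2d[:, :, None], shape[2], axis=2)

    band = (np.abs(xx - b1[:, None]) <= band_half_width) | \
           (np.abs(xx - b2[:, None]) <= band_half_width)
    calcein = np.where(band, 100.0, 0.0)[:, :, None] * np.ones((1, 1, shape[2]))

    boundary1 = np.repeat(b1[:, None], shape[2], axis=1)
    boundary2 = np.repeat(b2[:, None], shape[2], axis=1)
    calcein_vol = ImageVolume(calcein, tuple(vs), channel="calcein")
    mask = RegionMask(labels, tuple(vs), [boundary1, boundary2],
                      transcortical_axis=transcortical_axis,
                      endosteal_low=endosteal_low)
    return calcein_vol, mask


def shift_network(network: LCNetwork, offset) -> LCNetwork:
    """Copy of a network with all positions and polylines translated."""
    offset = np.asarray(offset, dtype=float)
    out = LCNetwork()
    for n in network.nodes():
        out.add_node(n, network.node_position(n) + offset, network.node_kind(n))
    for u, v, _k, geom in network.edges():
        out.add_edge(u, v, geom.polyline + offset, arc_length=geom.arc_length)
    return out


def merge_networks(*networks: LCNetwork) -> LCNetwork:
    """Disjoint union of networks with node ids relabelled sequentially."""
    out = LCNetwork()
    base = 0
    for net in networks:
        mapping = {}
        for n in net.nodes():
            mapping[n] = base
            out.add_node(base, net.node_position(n), net.node_kind(n))
            base += 1
        for u, v, _k, geom in net.edges():
            out.add_edge(mapping[u], mapping[v], geom.polyline,
                         arc_length=geom.arc_length)
    return out


# ---------------------------------------------------------------------------
# convenience: full synthetic sample


def generate_sample(spec: SyntheticSpec, imaging: ImagingSpec | None = None,
                    surfaces: tuple[SurfaceSpec, SurfaceSpec] | None = None):
    """Generate network, rendered rhodamine stack, calcein stack and masks.

    One-stop constructor for tests and the CLI ``simulate`` command.  The
    noise RNG is seeded from ``spec.seed`` via an independent child stream.
    """
    imaging = imaging if imaging is not None else ImagingSpec()
    net, gt = generate_network(spec)
    noise_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    rhodamine, pore_mask = render_volume(net, gt, imaging,
                                         canalicular_radius=spec.canalicular_radius,
                                         rng=noise_rng)
    if surfaces is None:
        width = spec.domain_size[1]
        surfaces = (SurfaceSpec(position=0.2 * width),
                    SurfaceSpec(position=0.8 * width))
    calcein, region_mask = generate_calcein_surfaces(
        spec.domain_size, surfaces, voxel_size=imaging.voxel_size)
    return {
        "network": net,
        "ground_truth": gt,
        "rhodamine": rhodamine,
        "pore_mask": pore_mask,
        "calcein": calcein,
        "region_mask": region_mask,
        "imaging": imaging,
        "spec": spec,
    }
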