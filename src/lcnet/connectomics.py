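"""Connectomic statistics of the lacuno-canalicular network.

The three headline parameters and their spatial analyses:

* **Can.Dn** — canalicular network density, the total canalicular length per
  unit bone volume (um/um^3), with lacunae and vascular canals excluded from
  the reference volume.  Edge lengths are *clipped*: each length increment of
  a finely resampled edge counts toward the sub-volume that contains it.
* **Can.Ln** — canalicular length, the spline arc length between two nodes.
  Length histograms use 1 um bins; canaliculi longer than 5 um are "long".
  For per-sub-volume histograms a whole edge is assigned to the cell holding
  its centre of mass (deliberately different from the clipped density rule —
  both are part of the method's definition).
* **DoC** — degree of connectivity of a node.  Junction nodes have at least
  three incident edges by definition; degree-3 nodes are "tree-like".

Spatial analyses: cubic sub-volume maps (default 5 um edge, 125 um^3 cells),
a convergence scan over cell sizes, normalized endosteal-to-periosteal
cortical profiles, and ordinary least-squares regressions of the long- and
tree-like percentages against the local density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    PORE_LACUNAR,
    PORE_VASCULAR,
    REGION_BACKGROUND,
    REGION_NAMES,
    BinaryVolume,
    ConnectomeSummary,
    CorticalProfile,
    Histogram,
    LCNetwork,
    RegionMask,
    RegressionResult,
    SubvolumeGrid,
    resample_polyline,
)

DEFAULT_SAMPLE_STEP = 0.1  # um, edge resampling for clipped length accumulation


# ---------------------------------------------------------------------------
# densities


def can_dn(network: LCNetwork, roi_volume: float,
           domain_size=None, step: float = DEFAULT_SAMPLE_STEP) -> float:
    """Canalicular network density: total (clipped) length / ROI volume.

    With ``domain_size`` set, edge length outside the axis-aligned domain
    [0, domain] is clipped away; otherwise all edge arc length counts.
    """
    if roi_volume <= 0:
        raise ValueError(f"roi_volume must be positive, got {roi_volume}")
    if network.n_edges == 0:
        return 0.0
    if domain_size is None:
        return network.total_length / roi_volume
    domain = np.asarray(domain_size, dtype=float)
    total = 0.0
    for *_uvk, geom in network.edges():
        mids, seg = resample_polyline(geom.polyline, step)
        if len(seg) == 0:
            continue
        inside = np.all((mids >= 0) & (mids <= domain), axis=1)
        total += float(seg[inside].sum())
    return total / roi_volume


def density_to_km_per_cm3(d: float) -> float:
    """Convert a density in um/um^3 to km/cm^3 (x 1000 by unit algebra)."""
    if d < 0:
        raise ValueError(f"density must be non-negative, got {d}")
    return d * 1000.0


# ---------------------------------------------------------------------------
# sub-volume grid


def _cell_shape(extent: np.ndarray, L: float) -> np.ndarray:
    return np.maximum(np.ceil(extent / L - 1e-9).astype(int), 1)


def subvolume_map(
    network: LCNetwork,
    mask: RegionMask | None = None,
    binary: BinaryVolume | None = None,
    edge_length: float = 5.0,
    domain_size=None,
    origin=None,
    step: float = DEFAULT_SAMPLE_STEP,
) -> SubvolumeGrid:
    """Partition the ROI into cubic sub-volumes and accumulate Can.Dn per cell.

    Every edge is resampled at ``step`` um and each length increment is added
    to the cell containing its midpoint (half-open cells; increments on the
    outer domain face fold into the last cell so total length is conserved).
    Per-cell V_ROI comes from the voxel grid when ``mask`` is given (region
    voxels minus lacunar/vascular voxels, times voxel volume), else from the
    geometric overlap of the cell with the domain.  Cells also receive the
    majority region label of their voxels.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    if mask is not None:
        extent = np.asarray(mask.labels.shape) * np.asarray(mask.voxel_size)
    elif domain_size is not None:
        extent = np.asarray(domain_size, dtype=float)
    else:
        raise ValueError("need a RegionMask or an explicit domain_size")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    shape = _cell_shape(extent, edge_length)
    n_cells = int(np.prod(shape))

    lengths = np.zeros(n_cells)
    for *_uvk, geom in network.edges():
        mids, seg = resample_polyline(geom.polyline, step)
        if len(seg) == 0:
            continue
        rel = mids - origin
        inside = np.all((rel >= 0) & (rel <= extent), axis=1)
        idx = np.floor(rel[inside] / edge_length).astype(int)
        idx = np.minimum(idx, shape - 1)
        flat = np.ravel_multi_index(idx.T, shape)
        np.add.at(lengths, flat, seg[inside])

    v_roi = np.zeros(n_cells)
    region = np.zeros(n_cells, dtype=np.uint8)
    if mask is not None:
        vs = np.asarray(mask.voxel_size)
        nvox = mask.labels.shape
        ax_idx = [np.minimum(
            np.floor(((np.arange(nvox[a]) + 0.5) * vs[a] - origin[a])
                     / edge_length).astype(int), shape[a] - 1)
            for a in range(3)]
        cell_of_voxel = (ax_idx[0][:, None, None] * (shape[1] * shape[2])
                         + ax_idx[1][None, :, None] * shape[2]
                         + ax_idx[2][None, None, :])
        include = mask.bone_mask
        if binary is not None and binary.class_labels is not None:
            include = include & ~((binary.class_labels == PORE_LACUNAR)
                                  | (binary.class_labels == PORE_VASCULAR))
        np.add.at(v_roi, cell_of_voxel[include].ravel(),
                  float(np.prod(vs)))
        # majority region label per cell (background excluded from the vote)
        counts = np.zeros((n_cells, 4), dtype=np.int64)
        lab = mask.labels
        for code in (1, 2, 3):
            sel = lab == code
            np.add.at(counts[:, code], cell_of_voxel[sel].ravel(), 1)
        region = np.where(counts[:, 1:].sum(axis=1) > 0,
                          counts[:, 1:].argmax(axis=1) + 1,
                          REGION_BACKGROUND).astype(np.uint8)
    else:
        # geometric V_ROI: product of per-axis overlaps of cell and domain
        per_axis = []
        for a in range(3):
            lo = np.arange(shape[a]) * edge_length
            hi = np.minimum(lo + edge_length, extent[a])
            per_axis.append(np.maximum(hi - lo, 0.0))
        v_roi = (per_axis[0][:, None, None]
                 * per_axis[1][None, :, None]
                 * per_axis[2][None, None, :]).ravel()

    return SubvolumeGrid(
        origin=origin,
        edge_length=float(edge_length),
        shape=tuple(int(s) for s in shape),
        lengths=lengths,
        v_roi=v_roi,
        region=region,
    )


def convergence_scan(
    network: LCNetwork,
    mask: RegionMask | None = None,
    binary: BinaryVolume | None = None,
    edge_lengths=tuple(range(1, 21)),
    domain_size=None,
    step: float = DEFAULT_SAMPLE_STEP,
) -> pd.DataFrame:
    """Scan sub-volume edge lengths and summarize the Can.Dn distribution.

    Returns one row per cell size L with the median, quartiles, mean and SD
    of the per-cell density over cells with V_ROI > 0, plus the summed
    clipped length (conserved across L up to the sampling step).
    """
    rows = []
    for L in edge_lengths:
        grid = subvolume_map(network, mask=mask, binary=binary,
                             edge_length=float(L), domain_size=domain_size,
                             step=step)
        d = grid.can_dn.ravel()
        d = d[np.isfinite(d)]
        rows.append({
            "L": float(L),
            "n_cells": int(d.size),
            "median": float(np.median(d)) if d.size else np.nan,
            "q25": float(np.percentile(d, 25)) if d.size else np.nan,
            "q75": float(np.percentile(d, 75)) if d.size else np.nan,
            "mean": float(d.mean()) if d.size else np.nan,
            "sd": float(d.std(ddof=1)) if d.size > 1 else np.nan,
            "total_length": grid.total_length(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scoping helpers


def _edge_table(network: LCNetwork, step: float = 0.5) -> pd.DataFrame:
    """Per-edge arc length and centre of mass (cached on the network)."""
    cache = getattr(network, "_edge_table_cache", None)
    if cache is not None and cache[0] == (network.n_edges, step):
        return cache[1]
    lengths = []
    coms = []
    for *_uvk, geom in network.edges():
        mids, seg = resample_polyline(geom.polyline, step)
        if len(seg) == 0 or seg.sum() <= 0:
            lengths.append(geom.arc_length)
            coms.append(geom.polyline.mean(axis=0))
            continue
        lengths.append(geom.arc_length)
        coms.append((mids * seg[:, None]).sum(axis=0) / seg.sum())
    df = pd.DataFrame({
        "length": np.asarray(lengths, dtype=float),
        "com0": np.asarray([c[0] for c in coms], dtype=float),
        "com1": np.asarray([c[1] for c in coms], dtype=float),
        "com2": np.asarray([c[2] for c in coms], dtype=float),
    })
    network._edge_table_cache = ((network.n_edges, step), df)
    return df


def _points_in_scope(points: np.ndarray, scope) -> np.ndarray:
    """Boolean selector for 3D points against a scope descriptor.

    ``scope`` is None (everything), ``("region", RegionMask, code)`` or
    ``("cell", SubvolumeGrid, (i, j, k))``.
    """
    if scope is None:
        return np.ones(len(points), dtype=bool)
    kind = scope[0]
    if kind == "region":
        _tag, mask, code = scope
        vs = np.asarray(mask.voxel_size)
        idx = np.floor(points / vs).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(mask.labels.shape)), axis=1)
        out = np.zeros(len(points), dtype=bool)
        out[ok] = mask.labels[tuple(idx[ok].T)] == code
        return out
    if kind == "cell":
        _tag, grid, cell = scope
        rel = points - grid.origin
        idx = np.floor(rel / grid.edge_length).astype(int)
        idx = np.minimum(idx, np.asarray(grid.shape) - 1)
        ok = np.all((rel >= 0), axis=1) & np.all(idx >= 0, axis=1)
        return ok & np.all(idx == np.asarray(cell), axis=1)
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# histograms


@dataclass
class LengthDistribution:
    """Can.Ln percentage histogram plus long-canaliculi fractions."""

    histogram: Histogram
    long_fraction_count: float
    long_fraction_length: float


def length_histogram(
    network: LCNetwork,
    scope=None,
    bin_width: float = 1.0,
    long_threshold: float = 5.0,
) -> LengthDistribution:
    """Percentage distribution of canalicular length (Can.Ln).

    Bins are half-open ``[k*w, (k+1)*w)`` um.  When scoped to a sub-volume
    cell, an edge belongs to the cell containing its centre of mass and its
    whole length counts there.  Long fractions are reported both
    count-weighted (share of edges longer than the threshold) and
    length-weighted (share of total length carried by those edges).
    """
    table = _edge_table(network)
    if len(table) == 0:
        return LengthDistribution(
            Histogram(np.arange(2, dtype=float) * bin_width,
                      np.zeros(1, dtype=int), np.zeros(1), 0, empty=True),
            np.nan, np.nan)
    coms = table[["com0", "com1", "com2"]].to_numpy()
    sel = _points_in_scope(coms, scope)
    lens = table["length"].to_numpy()[sel]
    if lens.size == 0:
        return LengthDistribution(
            Histogram(np.arange(2, dtype=float) * bin_width,
                      np.zeros(1, dtype=int), np.zeros(1), 0, empty=True),
            np.nan, np.nan)
    n_bins = int(np.floor(lens.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.minimum(np.floor(lens / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    percent = counts / counts.sum() * 100.0
    is_long = lens > long_threshold
    return LengthDistribution(
        Histogram(edges, counts, percent, int(lens.size)),
        float(is_long.mean()),
        float(lens[is_long].sum() / lens.sum()),
    )


@dataclass
class DocDistribution:
    """DoC percentage histogram over junction nodes plus tree-like fraction."""

    histogram: Histogram
    tree_like_fraction: float


def doc_histogram(network: LCNetwork, scope=None) -> DocDistribution:
    """Percentage distribution of the nodal degree of connectivity.

    Taken over junction nodes only (degree >= 3 by definition); lacunar and
    endpoint nodes are excluded.  The tree-like fraction is the share of
    junctions with the minimum degree 3.  An empty scope yields a flagged
    empty histogram.
    """
    juncs = [n for n in network.nodes(kind="junction")]
    if juncs:
        pos = np.asarray([network.node_position(n) for n in juncs])
        sel = _points_in_scope(pos, scope)
        degs = np.asarray([network.degree(n) for n in juncs], dtype=int)[sel]
    else:
        degs = np.zeros(0, dtype=int)
    if degs.size == 0:
        return DocDistribution(
            Histogram(np.arange(3, 5, dtype=float), np.zeros(1, dtype=int),
                      np.zeros(1), 0, empty=True), np.nan)
    dmax = int(degs.max())
    edges = np.arange(3, dmax + 2, dtype=float)
    counts = np.bincount(degs, minlength=dmax + 1)[3:]
    percent = counts / counts.sum() * 100.0
    return DocDistribution(
        Histogram(edges, counts, percent, int(degs.size)),
        float((degs == 3).mean()),
    )


# ---------------------------------------------------------------------------
# per-cell fractions and regressions


def cell_length_fractions(network: LCNetwork, grid: SubvolumeGrid,
                          long_threshold: float = 5.0) -> pd.DataFrame:
    """Per-cell long-canaliculi percentages (centre-of-mass assignment).

    Returns a DataFrame indexed by flat cell id with the number of assigned
    edges and the count- and length-weighted percentages of long canaliculi.
    """
    table = _edge_table(network)
    coms = table[["com0", "com1", "com2"]].to_numpy()
    lens = table["length"].to_numpy()
    rel = coms - grid.origin
    extent = np.asarray(grid.shape) * grid.edge_length
    inside = np.all((rel >= 0) & (rel <= extent), axis=1)
    idx = np.floor(rel[inside] / grid.edge_length).astype(int)
    idx = np.minimum(idx, np.asarray(grid.shape) - 1)
    flat = np.ravel_multi_index(idx.T, grid.shape)
    lens = lens[inside]
    is_long = lens > long_threshold
    n = np.bincount(flat, minlength=grid.n_cells)
    n_long = np.bincount(flat, weights=is_long, minlength=grid.n_cells)
    total_len = np.bincount(flat, weights=lens, minlength=grid.n_cells)
    long_len = np.bincount(flat, weights=lens * is_long, minlength=grid.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_count = np.where(n > 0, n_long / n * 100.0, np.nan)
        pct_length = np.where(total_len > 0, long_len / total_len * 100.0, np.nan)
    return pd.DataFrame({
        "n_edges": n,
        "pct_long_count": pct_count,
        "pct_long_length": pct_length,
    })


def cell_tree_fractions(network: LCNetwork, grid: SubvolumeGrid) -> pd.DataFrame:
    """Per-cell tree-like (DoC = 3) percentages over junction nodes."""
    juncs = list(network.nodes(kind="junction"))
    n = np.zeros(grid.n_cells, dtype=int)
    n_tree = np.zeros(grid.n_cells, dtype=int)
    if juncs:
        pos = np.asarray([network.node_position(j) for j in juncs])
        degs = np.asarray([network.degree(j) for j in juncs], dtype=int)
        rel = pos - grid.origin
        extent = np.asarray(grid.shape) * grid.edge_length
        inside = np.all((rel >= 0) & (rel <= extent), axis=1)
        idx = np.floor(rel[inside] / grid.edge_length).astype(int)
        idx = np.minimum(idx, np.asarray(grid.shape) - 1)
        flat = np.ravel_multi_index(idx.T, grid.shape)
        n = np.bincount(flat, minlength=grid.n_cells)
        n_tree = np.bincount(flat, weights=(degs[inside] == 3).astype(float),
                             minlength=grid.n_cells).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n > 0, n_tree / np.maximum(n, 1) * 100.0, np.nan)
    return pd.DataFrame({"n_junctions": n, "pct_tree": pct})


def density_connectivity_regression(
    grid: SubvolumeGrid,
    long_fractions: pd.DataFrame,
    tree_fractions: pd.DataFrame,
    weighting: str = "length",
) -> tuple[RegressionResult, RegressionResult]:
    """OLS fits of %long and %tree-like vs the per-cell density Can.Dn.

    Cells enter the %long fit when at least one edge is assigned to them and
    the %tree-like fit when they contain at least one junction node (both
    additionally require V_ROI > 0).  ``weighting`` selects the count- or
    length-weighted long percentage (length by default).
    """
    if weighting not in ("count", "length"):
        raise ValueError("weighting must be 'count' or 'length'")
    d = grid.can_dn.ravel()
    valid = grid.valid()

    col = "pct_long_length" if weighting == "length" else "pct_long_count"
    sel_long = valid & (long_fractions["n_edges"].to_numpy() >= 1)
    sel_tree = valid & (tree_fractions["n_junctions"].to_numpy() >= 1)

    def fit(x, y) -> RegressionResult:
        if x.size < 3:
            raise ValueError(
                f"need at least 3 eligible sub-volumes for a regression, got {x.size}")
        res = stats.linregress(x, y)
        return RegressionResult(float(res.slope), float(res.intercept),
                                float(res.rvalue ** 2), int(x.size))

    fit_long = fit(d[sel_long], long_fractions[col].to_numpy()[sel_long])
    fit_tree = fit(d[sel_tree], tree_fractions["pct_tree"].to_numpy()[sel_tree])
    return fit_long, fit_tree


# ---------------------------------------------------------------------------
# cortical profile


def cortical_profile(
    grid: SubvolumeGrid,
    mask: RegionMask,
    n_bins: int = 50,
) -> CorticalProfile:
    """Average Can.Dn along the normalized transcortical coordinate.

    Sub-volume columns (cells sharing a transcortical index) are averaged
    over the longitudinal and depth axes; column positions are normalized so
    0 is the endosteal and 1 the periosteal edge of the bone mask, and the
    profile is resampled to ``n_bins`` positions spanning [0, 1] inclusive.
    The two calcein surfaces are reported on the same normalized axis.
    """
    if len(mask.boundary_positions) < 2:
        raise ValueError("region mask lacks the two calcein surfaces")
    ax = mask.transcortical_axis
    vs = np.asarray(mask.voxel_size)

    bone_idx = np.nonzero(mask.bone_mask.any(axis=tuple(a for a in range(3)
                                                        if a != ax)))[0]
    if bone_idx.size == 0:
        raise ValueError("region mask contains no bone voxels")
    x_lo = bone_idx.min() * vs[ax]
    x_hi = (bone_idx.max() + 1) * vs[ax]

    def normalize(x_um: np.ndarray) -> np.ndarray:
        t = (x_um - x_lo) / (x_hi - x_lo)
        return t if mask.endosteal_low else 1.0 - t

    d = grid.can_dn.reshape(grid.shape)
    col_positions = []
    col_mean = []
    col_sd = []
    for ci in range(grid.shape[ax]):
        sl = [slice(None)] * 3
        sl[ax] = ci
        vals = d[tuple(sl)].ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        centre = grid.origin[ax] + (ci + 0.5) * grid.edge_length
        col_positions.append(float(normalize(np.asarray(centre))))
        col_mean.append(float(vals.mean()))
        col_sd.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    if not col_positions:
        raise ValueError("no sub-volumes with bone voxels to profile")
    order = np.argsort(col_positions)
    cp = np.asarray(col_positions)[order]
    cm = np.asarray(col_mean)[order]
    cs = np.asarray(col_sd)[order]

    positions = np.linspace(0.0, 1.0, n_bins)
    mean = np.interp(positions, cp, cm)
    sd = np.interp(positions, cp, cs)
    b1 = float(normalize(np.mean(mask.boundary_positions[0])))
    b2 = float(normalize(np.mean(mask.boundary_positions[1])))
    lo, hi = sorted((b1, b2))
    return CorticalProfile(positions, mean, sd, (lo, hi))


# ---------------------------------------------------------------------------
# summary


def summarize(
    network: LCNetwork,
    mask: RegionMask | None = None,
    binary: BinaryVolume | None = None,
    edge_length: float = 5.0,
    bin_width: float = 1.0,
    long_threshold: float = 5.0,
    domain_size=None,
    weighting: str = "length",
    profile_bins: int = 50,
) -> ConnectomeSummary:
    """Compute the full connectomic summary for one specimen / phantom."""
    from .segmentation import roi_volume as _roi_volume

    grid = subvolume_map(network, mask=mask, binary=binary,
                         edge_length=edge_length, domain_size=domain_size)
    d = grid.can_dn.ravel()
    valid = np.isfinite(d)

    if mask is not None:
        v_total = _roi_volume(mask, binary)
    else:
        v_total = float(grid.v_roi.sum())
    global_density = can_dn(network, v_total, domain_size=domain_size) \
        if v_total > 0 else np.nan

    by_region: dict[str, tuple[float, float, int]] = {}
    if mask is not None:
        for code in (1, 2, 3):
            sel = valid & (grid.region.ravel() == code)
            if sel.sum():
                by_region[REGION_NAMES[code]] = (
                    float(d[sel].mean()),
                    float(d[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
                    int(sel.sum()))

    ldist = length_histogram(network, bin_width=bin_width,
                             long_threshold=long_threshold)
    ddist = doc_histogram(network)

    long_fr = cell_length_fractions(network, grid, long_threshold=long_threshold)
    tree_fr = cell_tree_fractions(network, grid)
    try:
        reg_long, reg_tree = density_connectivity_regression(
            grid, long_fr, tree_fr, weighting=weighting)
    except ValueError:
        reg_long = reg_tree = None

    profile = None
    if mask is not None and len(mask.boundary_positions) >= 2:
        try:
            profile = cortical_profile(grid, mask, n_bins=profile_bins)
        except ValueError:
            profile = None

    return ConnectomeSummary(
        can_dn_global=float(global_density),
        can_dn_by_region=by_region,
        length_histogram=ldist.histogram,
        doc_histogram=ddist.histogram,
        long_fraction_count=ldist.long_fraction_count,
        long_fraction_length=ldist.long_fraction_length,
        tree_like_fraction=ddist.tree_like_fraction,
        regression_long=reg_long,
        regression_tree=reg_tree,
        profile=profile,
        metadata={
            "edge_length": edge_length,
            "bin_width": bin_width,
            "long_threshold": long_threshold,
            "n_edges": network.n_edges,
            "n_nodes": network.n_nodes,
            "total_length": network.total_length,
            "roi_volume": v_total,
        },
    )
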