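"""Shared data containers for the LCN connectome pipeline.

Axis convention
---------------
All voxel arrays are indexed ``(axis0, axis1, axis2)`` with the default
anatomical roles

* axis 0 — longitudinal (along the bone long axis; image rows),
* axis 1 — transcortical (endosteal to periosteal; image columns),
* axis 2 — depth (optical z; TIFF pages).

Physical positions are 3-vectors in micrometres in the same axis order.
Voxel ``(i, j, k)`` spans ``[i*s0, (i+1)*s0) x ...`` and its centre sits at
``((i+0.5)*s0, (j+0.5)*s1, (k+0.5)*s2)`` relative to the volume origin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

# ---------------------------------------------------------------------------
# label enumerations

REGION_BACKGROUND = 0
REGION_PERIOSTEAL_NEW = 1
REGION_INTERCORTEX = 2
REGION_ENDOSTEAL_NEW = 3

REGION_NAMES = {
    REGION_BACKGROUND: "background",
    REGION_PERIOSTEAL_NEW: "periosteal_new",
    REGION_INTERCORTEX: "intercortex",
    REGION_ENDOSTEAL_NEW: "endosteal_new",
}

PORE_CANALICULAR = 1
PORE_LACUNAR = 2
PORE_VASCULAR = 3

PORE_NAMES = {
    PORE_CANALICULAR: "canalicular",
    PORE_LACUNAR: "lacunar",
    PORE_VASCULAR: "vascular",
}

# segmentation provenance: which DoG pass detected a voxel
PASS_NONE = 0
PASS_THIN = 1
PASS_BULKY = 2
PASS_BOTH = 3


# ---------------------------------------------------------------------------
# image containers


@dataclass
class ImageVolume:
    """A single-channel 3D scalar image with physical voxel sizes (um)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "rhodamine"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite intensities")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def physical_extent(self) -> np.ndarray:
        """Domain extent in um along each axis."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)


@dataclass
class BinaryVolume:
    """Binarized porosity with per-voxel pore-class labels.

    ``provenance`` records which DoG pass fired (thin / bulky / both);
    ``class_labels`` is 0 on background and one of the ``PORE_*`` codes on
    foreground once :func:`lcnet.segmentation.classify_pores` has run.
    """

    foreground: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: np.ndarray | None = None
    class_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels)
            if np.any(self.class_labels[~self.foreground]):
                raise ValueError("class labels defined outside the foreground")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def class_mask(self, pore_class: int) -> np.ndarray:
        if self.class_labels is None:
            raise ValueError("pores have not been classified yet")
        return self.class_labels == pore_class


@dataclass
class RegionMask:
    """Anatomical partition of the cortex driven by the calcein labels.

    ``boundary_positions`` holds, for each of the two label surfaces, the
    transcortical coordinate (um) as a 2D array over (longitudinal, depth).
    Surfaces are ordered by increasing transcortical coordinate.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    boundary_positions: list[np.ndarray]
    transcortical_axis: int = 1
    endosteal_low: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.boundary_positions = [np.asarray(b, dtype=float) for b in self.boundary_positions]

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels != REGION_BACKGROUND

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region


def resample_polyline(poly: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Subdivide an (m, 3) polyline into pieces no longer than ``step``.

    Returns the midpoints and lengths of the pieces.  Each original segment
    is split on its own line, so the piece lengths sum to the polyline's arc
    length exactly (no corner cutting) — length accumulated into spatial
    bins is conserved to floating-point precision.
    """
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        return np.empty((0, 3)), np.empty(0)
    vec = np.diff(poly, axis=0)
    d = np.linalg.norm(vec, axis=1)
    keep = d > 0
    vec, d, starts = vec[keep], d[keep], poly[:-1][keep]
    if len(d) == 0:
        return np.empty((0, 3)), np.empty(0)
    counts = np.maximum(np.ceil(d / step).astype(int), 1)
    seg_idx = np.repeat(np.arange(len(d)), counts)
    offsets = np.arange(counts.sum()) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    frac = (offsets + 0.5) / counts[seg_idx]
    mids = starts[seg_idx] + frac[:, None] * vec[seg_idx]
    lengths = d[seg_idx] / counts[seg_idx]
    return mids, lengths


# ---------------------------------------------------------------------------
# the spatial network


@dataclass
class EdgeGeometry:
    """Geometry attached to one canaliculus (graph edge).

    ``polyline`` is an (m, 3) um sampling of the edge ordered from the source
    node to the target node; ``arc_length`` is Can.Ln in um.  ``tck`` is the
    scipy parametric-spline representation when the edge came out of spline
    fitting, else None (synthetic edges carry their exact polylines).
    """

    polyline: np.ndarray
    arc_length: float
    tck: tuple | None = None


class LCNetwork:
    """Spatial graph of the lacuno-canalicular network.

    Thin wrapper around a :class:`networkx.MultiGraph` (canaliculi may run in
    parallel between the same node pair, and a canaliculus can loop back onto
    its own junction).  Nodes carry ``position`` (um, 3-vector) and ``kind``
    in {"junction", "lacunar", "endpoint", "loop"}; edges carry an
    :class:`EdgeGeometry` under the key ``geometry``.
    """

    NODE_KINDS = ("junction", "lacunar", "endpoint", "loop")

    def __init__(self) -> None:
        self.graph = nx.MultiGraph()

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: int, position, kind: str) -> int:
        if kind not in self.NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(int(node_id), position=np.asarray(position, dtype=float), kind=kind)
        return int(node_id)

    def add_edge(self, u: int, v: int, polyline, arc_length: float | None = None,
                 tck: tuple | None = None) -> tuple[int, int, int]:
        polyline = np.asarray(polyline, dtype=float)
        if polyline.ndim != 2 or polyline.shape[1] != 3:
            raise ValueError("polyline must be (m, 3)")
        if arc_length is None:
            arc_length = float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))
        geom = EdgeGeometry(polyline=polyline, arc_length=float(arc_length), tck=tck)
        key = self.graph.add_edge(int(u), int(v), geometry=geom)
        return (int(u), int(v), key)

    # -- queries ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_position(self, node_id: int) -> np.ndarray:
        return self.graph.nodes[node_id]["position"]

    def node_kind(self, node_id: int) -> str:
        return self.graph.nodes[node_id]["kind"]

    def degree(self, node_id: int) -> int:
        return self.graph.degree(node_id)

    def nodes(self, kind: str | None = None) -> Iterator[int]:
        for n, data in self.graph.nodes(data=True):
            if kind is None or data["kind"] == kind:
                yield n

    def edges(self) -> Iterator[tuple[int, int, int, EdgeGeometry]]:
        for u, v, k, data in self.graph.edges(keys=True, data=True):
            yield u, v, k, data["geometry"]

    def edge_lengths(self) -> np.ndarray:
        return np.array([g.arc_length for *_ignored, g in self.edges()], dtype=float)

    @property
    def total_length(self) -> float:
        """Sum of edge arc lengths (um)."""
        return float(self.edge_lengths().sum()) if self.n_edges else 0.0

    def junction_degrees(self) -> np.ndarray:
        """Degrees of junction nodes (the DoC statistic's support)."""
        return np.array([self.degree(n) for n in self.nodes(kind="junction")], dtype=int)

    def new_node_id(self) -> int:
        return (max(self.graph.nodes) + 1) if self.graph.number_of_nodes() else 0


# ---------------------------------------------------------------------------
# sub-volume grid


@dataclass
class SubvolumeGrid:
    """Cubic partition of the ROI with per-cell canalicular density.

    ``lengths`` holds the clipped canalicular length per cell (um),
    ``v_roi`` the pore-excluded bone volume per cell (um^3) and ``can_dn``
    the per-cell density (um/um^3; NaN where ``v_roi`` is 0).  ``region``
    is the majority anatomical label per cell (REGION_* codes).
    """

    origin: np.ndarray
    edge_length: float
    shape: tuple[int, int, int]
    lengths: np.ndarray
    v_roi: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(n) for n in self.shape)

    @property
    def can_dn(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self.lengths / self.v_roi
        d = np.where(self.v_roi > 0, d, np.nan)
        return d

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_centres(self) -> np.ndarray:
        """(n_cells, 3) um centres in C order of the flattened grid."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.edge_length

    def valid(self) -> np.ndarray:
        """Boolean flat mask of cells that enter statistics (V_ROI > 0)."""
        return self.v_roi.ravel() > 0

    def total_length(self) -> float:
        return float(self.lengths.sum())


# ---------------------------------------------------------------------------
# result records


@dataclass
class Histogram:
    """A percentage histogram (Can.Ln or DoC style)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    percent: np.ndarray
    n: int
    empty: bool = False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class CorticalProfile:
    """Mean +- SD Can.Dn along the normalized endosteal (0) to periosteal (1)
    transcortical coordinate, with calcein boundary markers on the same axis."""

    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    boundaries: tuple[float, float]


@dataclass
class ConnectomeSummary:
    """Figure-ready bundle of the connectomic statistics."""

    can_dn_global: float
    can_dn_by_region: dict[str, tuple[float, float, int]]
    length_histogram: Histogram
    doc_histogram: Histogram
    long_fraction_count: float
    long_fraction_length: float
    tree_like_fraction: float
    regression_long: RegressionResult | None
    regression_tree: RegressionResult | None
    profile: CorticalProfile | None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(dataclasses.asdict(self))
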