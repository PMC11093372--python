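"""File formats, configuration and the end-to-end pipeline driver.

Formats: multi-page TIFF for image stacks (voxel size in ImageJ-style
metadata), GraphML plus node/edge/polyline CSV tables for networks, CSV for
sub-volume grids, histograms and profiles, JSON for summaries and YAML for
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import connectomics, netextract, segmentation, synthgen
from .types import (
    REGION_NAMES,
    ConnectomeSummary,
    ImageVolume,
    LCNetwork,
)

logger = logging.getLogger("lcnet")


# ---------------------------------------------------------------------------
# image stacks


def write_image_stack(path, volume: ImageVolume) -> None:
    """Write a volume as a multi-page TIFF with voxel-size metadata.

    Pages are depth slices; in-plane resolution goes into the TIFF
    resolution tags and the depth spacing into ImageJ metadata.
    """
    path = Path(path)
    s0, s1, s2 = volume.voxel_size
    data = np.moveaxis(volume.voxels, 2, 0)  # (depth, rows, cols)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / s1, 1.0 / s0),
        metadata={"spacing": s2, "unit": "um", "axes": "ZYX",
                  "channel": volume.channel},
    )


def read_image_stack(path, voxel_size=None, channel: str = "rhodamine") -> ImageVolume:
    """Read a multi-page TIFF into an ImageVolume (rows, cols, pages).

    Voxel sizes come from the TIFF/ImageJ metadata; ``voxel_size`` overrides
    them (required, with a logged warning, when the file has none).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a single-channel z-stack, "
                             f"got shape {data.shape}")
        meta_vs = _voxel_size_from_tiff(tf)
        meta_channel = None
        if tf.imagej_metadata:
            meta_channel = tf.imagej_metadata.get("channel")
    volume = np.moveaxis(data, 0, 2).astype(np.float64)
    if voxel_size is None:
        if meta_vs is None:
            raise ValueError(
                f"{path}: no voxel_size metadata found and no override given "
                f"(field 'voxel_size')")
        voxel_size = meta_vs
    elif meta_vs is None:
        logger.warning("%s: missing voxel-size metadata, using override %s",
                       path, voxel_size)
    return ImageVolume(volume, tuple(voxel_size), channel=meta_channel or channel)


def _voxel_size_from_tiff(tf: "tifffile.TiffFile"):
    try:
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        s1 = xres[1] / xres[0]
        s0 = yres[1] / yres[0]
        spacing = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            spacing = float(tf.imagej_metadata["spacing"])
        if spacing is None or s0 <= 0 or s1 <= 0:
            return None
        return (float(s0), float(s1), spacing)
    except (KeyError, ZeroDivisionError, IndexError, TypeError):
        return None


# ---------------------------------------------------------------------------
# networks


def write_network(path_prefix, network: LCNetwork) -> None:
    """Write a network as GraphML plus node/edge/polyline CSV tables.

    ``path_prefix`` may be a directory or a file prefix; files are
    ``<prefix>.graphml``, ``<prefix>_nodes.csv``, ``<prefix>_edges.csv`` and
    ``<prefix>_polylines.csv``.  The round trip is lossless for topology,
    positions, kinds and arc lengths.
    """
    prefix = Path(path_prefix)
    if prefix.is_dir():
        prefix = prefix / "network"
    prefix.parent.mkdir(parents=True, exist_ok=True)

    g = nx.MultiGraph()
    node_rows = []
    for n in network.nodes():
        p = network.node_position(n)
        kind = network.node_kind(n)
        g.add_node(n, x=float(p[0]), y=float(p[1]), z=float(p[2]), kind=kind)
        node_rows.append({"id": n, "x": p[0], "y": p[1], "z": p[2],
                          "kind": kind, "degree": network.degree(n)})
    edge_rows = []
    poly_rows = []
    for eid, (u, v, k, geom) in enumerate(network.edges()):
        g.add_edge(u, v, key=k, edge_id=eid, arc_length=float(geom.arc_length))
        edge_rows.append({"id": eid, "source": u, "target": v, "key": k,
                          "arc_length": repr(float(geom.arc_length)),
                          "n_points": len(geom.polyline)})
        for pi, pt in enumerate(geom.polyline):
            poly_rows.append({"edge_id": eid, "point": pi,
                              "x": pt[0], "y": pt[1], "z": pt[2]})
    nx.write_graphml(g, str(prefix) + ".graphml")
    pd.DataFrame(node_rows, columns=["id", "x", "y", "z", "kind", "degree"]) \
        .to_csv(str(prefix) + "_nodes.csv", index=False)
    pd.DataFrame(edge_rows, columns=["id", "source", "target", "key",
                                     "arc_length", "n_points"]) \
        .to_csv(str(prefix) + "_edges.csv", index=False)
    pd.DataFrame(poly_rows, columns=["edge_id", "point", "x", "y", "z"]) \
        .to_csv(str(prefix) + "_polylines.csv", index=False,
                float_format="%.17g")


def read_network(path_prefix) -> LCNetwork:
    """Read a network written by :func:`write_network`."""
    prefix = Path(path_prefix)
    if prefix.is_dir():
        prefix = prefix / "network"
    g = nx.read_graphml(str(prefix) + ".graphml", node_type=int,
                        force_multigraph=True)
    edges = pd.read_csv(str(prefix) + "_edges.csv",
                        dtype={"arc_length": np.float64})
    polys = pd.read_csv(str(prefix) + "_polylines.csv")

    net = LCNetwork()
    for n, data in g.nodes(data=True):
        net.add_node(n, (data["x"], data["y"], data["z"]), data["kind"])
    known = set(net.graph.nodes)
    poly_groups = dict(tuple(polys.groupby("edge_id"))) if len(polys) else {}
    for row in edges.itertuples():
        if row.source not in known or row.target not in known:
            raise ValueError(
                f"edge {row.id} references unknown node "
                f"{row.source if row.source not in known else row.target}")
        grp = poly_groups.get(row.id)
        if grp is None:
            p_u = net.node_position(row.source)
            p_v = net.node_position(row.target)
            poly = np.vstack([p_u, p_v])
        else:
            grp = grp.sort_values("point")
            poly = grp[["x", "y", "z"]].to_numpy()
        net.add_edge(row.source, row.target, poly, arc_length=row.arc_length)
    return net


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything needed to (re)run the pipeline end to end.

    Defaults follow the method's canonical values: 5 um sub-volumes, 1 um
    Can.Ln bins, a 5 um long-canaliculus threshold, order-3 splines and a
    minimum junction degree of 3.
    """

    # inputs: either image stacks ...
    rhodamine_path: str | None = None
    calcein_path: str | None = None
    voxel_size: tuple[float, float, float] | None = None
    # ... or a synthetic phantom
    synthetic: dict | None = None
    imaging: dict | None = None

    # segmentation
    canalicular_dog: dict = field(default_factory=dict)
    lacunar_dog: dict = field(default_factory=dict)
    lacuna_min: float = 100.0
    lacuna_max: float = 300.0
    vascular_span: float = 20.0

    # network extraction
    merge_radius: int = 1
    prune_length: float = 1.0
    spline_smoothing: float = 0.2

    # connectomics
    subvolume_edge: float = 5.0
    bin_width: float = 1.0
    long_threshold: float = 5.0
    convergence_lengths: tuple = ()
    weighting: str = "length"
    profile_bins: int = 50

    output_dir: str = "lcnet_out"
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


# ---------------------------------------------------------------------------
# pipeline


def _dog_params(defaults: segmentation.DoGParams, override: dict
                ) -> segmentation.DoGParams:
    kwargs = dataclasses.asdict(defaults)
    kwargs.update(override or {})
    return segmentation.DoGParams(**kwargs)


def run_pipeline(config: PipelineConfig) -> ConnectomeSummary:
    """Run synthgen (if requested) -> segmentation -> extraction -> statistics.

    Writes the echoed config, network files, the sub-volume grid, histograms,
    the cortical profile and a summary JSON into ``config.output_dir`` and
    returns the in-memory summary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    logging.basicConfig(level=config.verbosity.upper())

    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _T()

    ground_truth = None
    domain_size = None
    with stage("input"):
        if config.synthetic is not None:
            spec = synthgen.SyntheticSpec(**{**config.synthetic,
                                             "seed": config.synthetic.get(
                                                 "seed", config.seed)})
            imaging = synthgen.ImagingSpec(**(config.imaging or {}))
            sample = synthgen.generate_sample(spec, imaging)
            rhodamine = sample["rhodamine"]
            calcein = sample["calcein"]
            ground_truth = sample["ground_truth"]
            domain_size = spec.domain_size
            write_image_stack(out / "rhodamine.tif", rhodamine)
            write_image_stack(out / "calcein.tif", calcein)
        elif config.rhodamine_path is not None:
            rhodamine = read_image_stack(config.rhodamine_path,
                                         voxel_size=config.voxel_size)
            calcein = (read_image_stack(config.calcein_path,
                                        voxel_size=config.voxel_size,
                                        channel="calcein")
                       if config.calcein_path else None)
        else:
            raise ValueError("config needs either synthetic parameters or "
                             "a rhodamine stack path")

    with stage("segmentation"):
        binary = segmentation.dog_binarize(
            rhodamine,
            canalicular_params=_dog_params(segmentation.CANALICULAR_DOG,
                                           config.canalicular_dog),
            lacunar_params=_dog_params(segmentation.LACUNAR_DOG,
                                       config.lacunar_dog))
        binary = segmentation.classify_pores(
            binary, lacuna_min=config.lacuna_min, lacuna_max=config.lacuna_max,
            vascular_span=config.vascular_span)
        mask = None
        if calcein is not None:
            mask = segmentation.build_region_mask(calcein)

    with stage("extraction"):
        network = netextract.extract_network(
            binary, merge_radius=config.merge_radius,
            prune_length=config.prune_length,
            smoothing=config.spline_smoothing)
        write_network(out / "network", network)

    with stage("quantification"):
        summary = connectomics.summarize(
            network, mask=mask, binary=binary,
            edge_length=config.subvolume_edge,
            bin_width=config.bin_width,
            long_threshold=config.long_threshold,
            domain_size=domain_size,
            weighting=config.weighting,
            profile_bins=config.profile_bins)
        grid = connectomics.subvolume_map(
            network, mask=mask, binary=binary,
            edge_length=config.subvolume_edge, domain_size=domain_size)
        write_subvolume_grid(out / "subvolumes.csv", grid)
        write_histograms(out, summary)
        if summary.profile is not None:
            write_profile(out / "profile.csv", summary.profile)
        if config.convergence_lengths:
            scan = connectomics.convergence_scan(
                network, mask=mask, binary=binary,
                edge_lengths=config.convergence_lengths,
                domain_size=domain_size)
            scan.to_csv(out / "convergence.csv", index=False)

    summary.metadata.update({
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    })
    if ground_truth is not None:
        summary.metadata["ground_truth"] = {
            "total_length": ground_truth.total_length,
            "density": ground_truth.total_length / float(np.prod(domain_size)),
            "seed_streams": ground_truth.seed_streams,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    logger.info("pipeline done: %s", {k: round(v, 2) for k, v in timings.items()})
    return summary


# ---------------------------------------------------------------------------
# table writers


def write_subvolume_grid(path, grid) -> None:
    centres = grid.cell_centres()
    idx = np.indices(grid.shape).reshape(3, -1)
    pd.DataFrame({
        "i": idx[0], "j": idx[1], "k": idx[2],
        "x": centres[:, 0], "y": centres[:, 1], "z": centres[:, 2],
        "length_um": grid.lengths,
        "v_roi_um3": grid.v_roi,
        "can_dn": grid.can_dn.ravel(),
        "region": [REGION_NAMES[int(r)] for r in grid.region.ravel()],
    }).to_csv(path, index=False)


def write_histograms(out_dir, summary: ConnectomeSummary) -> None:
    out_dir = Path(out_dir)
    lh = summary.length_histogram
    pd.DataFrame({
        "bin_lo": lh.bin_edges[:-1], "bin_hi": lh.bin_edges[1:],
        "count": lh.counts, "percent": lh.percent,
    }).to_csv(out_dir / "length_histogram.csv", index=False)
    dh = summary.doc_histogram
    pd.DataFrame({
        "degree": dh.bin_edges[:-1].astype(int),
        "count": dh.counts, "percent": dh.percent,
    }).to_csv(out_dir / "doc_histogram.csv", index=False)


def write_profile(path, profile) -> None:
    pd.DataFrame({
        "position": profile.positions,
        "mean_can_dn": profile.mean,
        "sd_can_dn": profile.sd,
    }).to_csv(path, index=False)
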