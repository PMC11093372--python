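"""Shared phantoms for the test suite.

The expensive end-to-end phantom (acceptance geometry: 50 x 50 x 30 um at
0.2 um/um^3, rendered noise-free at the default resolution and pushed through
segmentation and network extraction) is built once per session and shared by
the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lcnet import netextract, segmentation, synthgen
from lcnet.types import BinaryVolume, LCNetwork


def make_tube_network(points_list, domain_size):
    """LCNetwork from explicit polylines (endpoint nodes at the extremes)."""
    net = LCNetwork()
    nid = 0
    for pts in points_list:
        pts = np.asarray(pts, dtype=float)
        net.add_node(nid, pts[0], "endpoint")
        net.add_node(nid + 1, pts[-1], "endpoint")
        net.add_edge(nid, nid + 1, pts)
        nid += 2
    gt = synthgen.GroundTruth(network=net, total_length=net.total_length,
                              per_cell_lengths={}, lacunae=[],
                              domain_size=tuple(domain_size))
    return net, gt


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


NOISE_FREE = dict(psf_sigma=(0.0, 0.0, 0.0), noise_model="none")


@pytest.fixture(scope="session")
def acceptance_sample():
    """Full noise-free pipeline on the 50x50x30 um, 0.2 um/um^3 phantom."""
    spec = synthgen.SyntheticSpec(target_density=0.2, seed=1)
    network, truth = synthgen.generate_network(spec)
    imaging = synthgen.ImagingSpec(**NOISE_FREE)
    image, pore_mask = synthgen.render_volume(
        network, truth, imaging, canalicular_radius=spec.canalicular_radius)
    binary = segmentation.classify_pores(segmentation.dog_binarize(image))
    extracted = netextract.extract_network(binary)
    return {
        "spec": spec,
        "truth_network": network,
        "truth": truth,
        "image": image,
        "pore_mask": pore_mask,
        "binary": binary,
        "extracted": extracted,
    }


@pytest.fixture(scope="session")
def y_phantom():
    """Three 8 um tubes meeting at one point, rendered and binarized."""
    centre = np.array([10.0, 10.0, 5.0])
    dirs = [np.array([0, 1.0, 0]),
            np.array([0.866, -0.5, 0]),
            np.array([-0.866, -0.5, 0])]
    net = LCNetwork()
    net.add_node(0, centre, "junction")
    for i, d in enumerate(dirs):
        tip = centre + 8.0 * d
        net.add_node(i + 1, tip, "endpoint")
        net.add_edge(0, i + 1, np.vstack([centre, tip]))
    gt = synthgen.GroundTruth(network=net, total_length=24.0,
                              per_cell_lengths={}, lacunae=[],
                              domain_size=(20.0, 20.0, 10.0))
    imaging = synthgen.ImagingSpec(voxel_size=(0.3, 0.3, 0.3), **NOISE_FREE)
    image, mask = synthgen.render_volume(net, gt, imaging, canalicular_radius=0.5)
    return {"network": net, "truth": gt, "image": image, "mask": mask,
            "binary": BinaryVolume(mask > 0, (0.3, 0.3, 0.3))}
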