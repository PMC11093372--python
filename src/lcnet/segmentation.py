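"""Segmentation of rhodamine-stained LCN stacks and calcein region masks.

Binarization uses a dual-pass adaptive Difference-of-Gaussians (DoG): one
band-pass tuned to sub-micrometre canaliculi, a second to the bulkier
(micrometre-scale) lacunae and vascular canals.  The adaptive part is a
per-voxel threshold of the DoG response against a local response scale, which
makes the detection robust to the slow intensity trends of confocal depth
series and exactly invariant to additive intensity offsets.

Pore classification separates lacunae and vascular canals (excluded from the
reference volume of Can.Dn) from canaliculi using component volume and
extent; the calcein channel partitions the cortex into newly formed
(periosteal / endosteal) and pre-existing bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import (
    PASS_BOTH,
    PASS_BULKY,
    PASS_THIN,
    PORE_CANALICULAR,
    PORE_LACUNAR,
    PORE_VASCULAR,
    REGION_BACKGROUND,
    REGION_ENDOSTEAL_NEW,
    REGION_INTERCORTEX,
    REGION_PERIOSTEAL_NEW,
    BinaryVolume,
    ImageVolume,
    RegionMask,
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DoGParams:
    """One DoG pass: band-pass sigmas (um) and the adaptive threshold.

    The DoG response is normalized per voxel by its local maximum in a
    ``window`` um box, which makes the detection insensitive to slow
    amplitude trends (e.g. residual depth attenuation): a voxel is
    foreground where ``response >= threshold x local_max(response)`` and the
    response clears a robust noise floor (``noise_mult`` x the MAD-based
    background scale, and ``floor_rel`` x the global response peak).
    """

    sigma_small: float
    sigma_large: float
    threshold: float = 0.5
    window: float = 10.0
    noise_mult: float = 3.0
    floor_contrast: float = 0.1
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.sigma_small <= 0 or self.sigma_large <= 0:
            raise ValueError("DoG sigmas must be positive")
        if self.sigma_small >= self.sigma_large:
            raise ValueError("sigma_small must be < sigma_large")


# Scale-matched defaults: sigma_small ~ half the expected structure radius.
# The bulky pass needs a higher contrast floor (a sub-um tube still leaves a
# weak response in the lacunar band) and hole filling (the DoG response of a
# blob much wider than sigma_small is a shell, not a filled volume).
CANALICULAR_DOG = DoGParams(sigma_small=0.15, sigma_large=0.6,
                            threshold=0.3, floor_contrast=0.05)
LACUNAR_DOG = DoGParams(sigma_small=1.5, sigma_large=6.0,
                        threshold=0.3, floor_contrast=0.2, fill_holes=True)


def _dog_response(image: ImageVolume, params: DoGParams) -> np.ndarray:
    vs = np.asarray(image.voxel_size)
    img = image.voxels.astype(np.float64)
    lo = ndimage.gaussian_filter(img, sigma=params.sigma_small / vs)
    hi = ndimage.gaussian_filter(img, sigma=params.sigma_large / vs)
    return lo - hi


def _single_pass(image: ImageVolume, params: DoGParams) -> np.ndarray:
    if np.ptp(image.voxels) == 0:  # constant image: nothing to detect
        return np.zeros(image.shape, dtype=bool)
    resp = _dog_response(image, params)
    vs = np.asarray(image.voxel_size)
    size = tuple(int(max(s, 3)) | 1 for s in params.window / vs)
    local_max = ndimage.maximum_filter(resp, size=size)
    noise_scale = 1.4826 * float(np.median(np.abs(resp)))  # background MAD
    floor = max(params.noise_mult * noise_scale,
                params.floor_contrast * float(np.ptp(image.voxels)))
    fg = (resp >= params.threshold * local_max) & (resp > floor)
    if params.fill_holes and fg.any():
        fg = ndimage.binary_closing(fg, structure=_STRUCT26)
        fg = ndimage.binary_fill_holes(fg)
    return fg


def dog_binarize(
    image: ImageVolume,
    canalicular_params: DoGParams = CANALICULAR_DOG,
    lacunar_params: DoGParams = LACUNAR_DOG,
) -> BinaryVolume:
    """Binarize a rhodamine stack with the thin + bulky DoG passes.

    The foreground is the union of the two passes; per-voxel provenance
    (which pass fired) is kept so that pore classification can reason about
    bulky structures without absorbing attached canaliculi.
    """
    thin = _single_pass(image, canalicular_params)
    bulky = _single_pass(image, lacunar_params)
    provenance = np.zeros(image.shape, dtype=np.uint8)
    provenance[thin] = PASS_THIN
    provenance[bulky] = PASS_BULKY
    provenance[thin & bulky] = PASS_BOTH
    return BinaryVolume(
        foreground=thin | bulky,
        voxel_size=image.voxel_size,
        provenance=provenance,
    )


def classify_pores(
    binary: BinaryVolume,
    lacuna_min: float = 100.0,
    lacuna_max: float = 300.0,
    vascular_span: float = 20.0,
) -> BinaryVolume:
    """Label foreground voxels as canalicular, lacunar or vascular.

    Connected components of the *bulky-pass* detection are measured in
    physical units: compact blobs in the lacunar volume range
    (``lacuna_min``..``lacuna_max`` um^3, lacunae being ~100-250 um^3)
    become lacunar; anything larger, or spanning more than ``vascular_span``
    um along an axis, becomes vascular.  All remaining foreground —
    including thin canaliculi attached to a lacuna — stays canalicular.
    Idempotent: re-running on a classified volume gives the same labels.
    """
    fg = binary.foreground
    labels = np.zeros(fg.shape, dtype=np.uint8)
    labels[fg] = PORE_CANALICULAR
    if binary.provenance is not None:
        bulky = (binary.provenance == PASS_BULKY) | (binary.provenance == PASS_BOTH)
    else:
        bulky = fg
    voxvol = binary.voxel_volume
    vs = np.asarray(binary.voxel_size)
    comp, n = ndimage.label(bulky, structure=_STRUCT26)
    if n:
        sizes = ndimage.sum_labels(bulky.astype(np.float64), comp,
                                   index=np.arange(1, n + 1)) * voxvol
        slices = ndimage.find_objects(comp)
        for ci, (size, slc) in enumerate(zip(sizes, slices), start=1):
            if size < lacuna_min:
                continue
            span = max((s.stop - s.start) * vs[ax] for ax, s in enumerate(slc))
            cls = PORE_VASCULAR if (size > lacuna_max or span > vascular_span) \
                else PORE_LACUNAR
            labels[comp == ci] = cls
    return BinaryVolume(
        foreground=fg,
        voxel_size=binary.voxel_size,
        provenance=binary.provenance,
        class_labels=labels,
    )


# ---------------------------------------------------------------------------
# calcein region mask


class CalceinBandError(ValueError):
    pass


def _fill_nan_nearest(arr: np.ndarray) -> np.ndarray:
    """Replace NaNs with the nearest finite value (2D)."""
    nanmask = np.isnan(arr)
    if not nanmask.any():
        return arr
    if nanmask.all():
        raise CalceinBandError("calcein band has no detected voxels")
    idx = ndimage.distance_transform_edt(nanmask, return_distances=False,
                                         return_indices=True)
    return arr[tuple(idx)]


def build_region_mask(
    calcein: ImageVolume,
    bone_mask: np.ndarray | None = None,
    threshold: float | None = None,
    min_band_fraction: float = 0.2,
    smoothing: float = 2.0,
    transcortical_axis: int = 1,
    endosteal_low: bool = True,
) -> RegionMask:
    """Partition the cortex into three regions from the calcein label bands.

    The calcein channel is thresholded (Otsu by default), the two largest
    band components crossing the cortex are kept, and a smooth surface (the
    intensity-weighted transcortical centroid per (longitudinal, depth)
    column, Gaussian-smoothed) is fitted to each.  Voxels of the bone mask
    below the first surface / between / above the second get the endosteal,
    intercortex and periosteal labels (orientation set by ``endosteal_low``).
    """
    if transcortical_axis != 1:
        raise NotImplementedError("only transcortical axis 1 is supported")
    img = calcein.voxels
    if bone_mask is None:
        bone_mask = np.ones(img.shape, dtype=bool)
    if bone_mask.shape != img.shape:
        raise ValueError("bone mask shape does not match the calcein stack")
    if threshold is None:
        if np.ptp(img) == 0:
            raise CalceinBandError("calcein channel is constant: no label bands "
                                   "(missing both endosteal and periosteal bands)")
        threshold = float(threshold_otsu(img))
    bands = img > threshold
    comp, n = ndimage.label(bands, structure=_STRUCT26)
    if n < 2:
        missing = "both bands" if n == 0 else "the second band"
        raise CalceinBandError(
            f"found {n} calcein band component(s); {missing} missing")
    sizes = ndimage.sum_labels(bands.astype(np.float64), comp,
                               index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1

    _n0, n1, _n2 = img.shape
    vs = np.asarray(calcein.voxel_size)
    surfaces = []
    for ci in keep:
        m = comp == ci
        cols = m.sum(axis=1)  # (n0, n2) voxels per transcortical column
        if (cols > 0).mean() < min_band_fraction:
            raise CalceinBandError(
                "a calcein band does not cross enough of the cortex section")
        x_idx = np.arange(n1)[None, :, None]
        w = m * img
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cen = (w * x_idx).sum(axis=1) / wsum
        cen = np.where(wsum > 0, cen, np.nan)
        cen = _fill_nan_nearest(cen)
        cen = ndimage.gaussian_filter(cen, sigma=smoothing)
        surfaces.append((cen + 0.5) * vs[1])  # um position of the band centre
    surfaces.sort(key=lambda s: float(np.mean(s)))
    b1, b2 = surfaces
    if np.any(b1 >= b2):
        raise CalceinBandError("fitted calcein surfaces intersect")

    x_um = (np.arange(n1) + 0.5) * vs[1]
    labels = np.full(img.shape, REGION_INTERCORTEX, dtype=np.uint8)
    low_label = REGION_ENDOSTEAL_NEW if endosteal_low else REGION_PERIOSTEAL_NEW
    high_label = REGION_PERIOSTEAL_NEW if endosteal_low else REGION_ENDOSTEAL_NEW
    xcmp = x_um[None, :, None]
    labels[xcmp < b1[:, None, :]] = low_label
    labels[xcmp >= b2[:, None, :]] = high_label
    labels[~bone_mask] = REGION_BACKGROUND
    return RegionMask(labels, calcein.voxel_size, [b1, b2],
                      transcortical_axis=transcortical_axis,
                      endosteal_low=endosteal_low)


def roi_volume(mask: RegionMask, binary: BinaryVolume | None,
               region: int | None = None) -> float:
    """Reference volume for Can.Dn: region volume minus lacunar/vascular pores.

    ``region`` is one of the REGION_* codes or None for the whole bone mask.
    Canalicular voxels stay inside the reference volume; only lacunae and
    vascular canals are excluded.
    """
    sel = mask.bone_mask if region is None else mask.region_mask(region)
    if binary is not None:
        if binary.foreground.shape != mask.labels.shape:
            raise ValueError("binary volume grid does not match the region mask")
        if binary.class_labels is not None:
            pores = (binary.class_labels == PORE_LACUNAR) | \
                    (binary.class_labels == PORE_VASCULAR)
            sel = sel & ~pores
    return float(sel.sum()) * mask.voxel_volume
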