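# Methods

This note documents the models and numerical choices behind `lcnet`: what
each stage assumes, which parameters matter, and what a green test does and
does not establish.

## Coordinate and unit conventions

All voxel arrays are `(axis0, axis1, axis2)` = (longitudinal, transcortical,
depth); physical positions are µm 3-vectors in the same order, with voxel
`(i, j, k)` centred at `((i+0.5)s0, (j+0.5)s1, (k+0.5)s2)`. The default
voxel size is (0.303, 0.303, 0.27) µm: a 100× confocal objective gives
303 nm in-plane pixels, and ~110 optical slices over a 30 µm depth give
0.27 µm axial spacing. All geometry downstream of the image (skeleton
chains, splines, densities) is carried in physical units, so anisotropic
voxels are handled throughout.

## Synthetic phantom generator (`synthgen`)

The generator's role is to produce networks whose statistical structure the
analysis assumes — tree-dominated branching (junction degree 3), canalicular
lengths of a few µm with most below 5 µm, and spatially varying density —
while staying *resolvable* at the imaging resolution, so that disagreement
between extracted and true statistics indicts the pipeline, not the phantom.

**Growth model.** Ellipsoidal lacunae (default 6 × 3 × 2 µm semi-axes,
151 µm³, inside the murine 100–250 µm³ range; default 6 per 50 × 50 × 30 µm,
matching murine lacunar number densities of ~(4–9)·10⁴ mm⁻³) seed random
walkers from uniformly drawn surface points. A walker advances in 0.25 µm
steps with von Mises-like direction noise (`tortuosity`, default 0.08 rad
per step) and terminates when its segment-length budget
(N(8, 4²) µm, clipped below at 2 µm) runs out, when it leaves the domain
(clipped to the boundary), or when it is sterically trapped. Branch events
fire as a Poisson process along the arc (`branch_rate`, default 1.4 µm⁻¹)
after a refractory distance (`branch_refractory`, default 1.6 µm, which also
keeps consecutive junctions farther apart than the imaging resolution);
each event creates a degree-3 junction and two daughters splayed ±~35°
around the parent direction. Ground-truth junction degree is therefore
exactly 3 everywhere; higher degrees can only be produced deliberately by
composing networks.

**Steric avoidance.** Real canaliculi are distinct channels; two tubes
closer than the imaging resolution would fuse in the rendered stack and
create junctions that exist in no ground truth. Walkers therefore may not
come within `min_separation` (default 1.0 µm — the empirically measured
separability limit for 0.3 µm-radius tubes at the default voxel size) of any
previously laid tube sample, including other branches of their own tree.
Exempt are only a walker's own trailing 2.5 µm and samples within 1.5 µm of
its birth point (its parent edge and its sibling's first steps). The
response to an approaching obstacle is sliding (the approaching velocity
component is removed and a small outward bias added, the way processes
fasciculate); a walker that cannot find a free direction terminates. Branch
events are only accepted when probe points at 0.9/1.7/2.5 µm along both
daughter directions are clear and inside the domain — otherwise the
canaliculus simply keeps running — which keeps sub-resolution stub branches
out of the ground truth.

**Density control.** With `target_density` set, whole canalicular trees are
added round-robin over the lacunae until the total edge length reaches
`target × volume`; a long run of barren sprouts (surface sites all within
`min_separation` of existing tubes) declares the domain saturated. The
achieved density is within 5% of the target whenever feasible, else
`InfeasibleDensityError` reports what was reached. At the reference
conditions (0.20 µm/µm³, 50 × 50 × 30 µm) the controller lands within
±4% across seeds.

**Rendering.** Membership is exact: a voxel is canalicular foreground iff
its centre lies within `canalicular_radius` (default 0.3 µm; the true
radius is optically unresolvable and is a free parameter) of an edge
polyline, lacunar iff inside an ellipsoid. The ground-truth mask is taken
at this point; PSF blur (Gaussian, default σ = (0.15, 0.15, 0.45) µm),
depth attenuation (`(1 − a)^depth`) and noise (Poisson photons + Gaussian
read noise by default) are applied afterwards. Rendering refuses grids
beyond a voxel budget (~134 M voxels) rather than swapping.

**Calcein channel.** Two label surfaces (planar or sinusoidal functions of
the longitudinal coordinate) partition the cortex into newly formed bone at
the endosteal face, intercortex, and newly formed bone at the periosteal
face; the channel itself contains thin bright bands at the surfaces.

**What the phantom does not emulate:** stitching artefacts, woven- vs
lamellar-bone texture, vascular canals (tested with geometric stand-ins
only), micro-crack or soft-tissue staining, and anisotropic canalicular
orientation distributions. A green recovery test therefore establishes that
the pipeline measures resolvable tube networks correctly — not that every
biological confound is handled.

## Segmentation (`segmentation`)

Two Difference-of-Gaussians band-passes: a thin pass (σ = 0.15/0.6 µm)
matched to canaliculi and a bulky pass (σ = 1.5/6 µm) matched to lacunae.
The adaptive threshold is per voxel: a voxel is foreground where the DoG
response exceeds `threshold ×` its local maximum in a 10 µm window *and* a
robust floor (`noise_mult ×` the MAD-based background scale and
`floor_contrast ×` the image contrast range). Normalizing by the local
response maximum makes detection insensitive to residual slow amplitude
trends (depth attenuation), and because everything is computed on the DoG
response, binarization is exactly invariant to additive intensity offsets.
Defaults (thin: threshold 0.3, floor 0.05; bulky: threshold 0.3, floor 0.2)
were chosen jointly on noise-free and noisy phantoms to keep single-tube
detection exact, lacunar volumes near truth, and length recovery high under
the default PSF/noise model. The bulky pass closes and fills its detections
(a blob much wider than the band-pass scale responds as a shell).

Pore classification labels 26-connected bulky components by physical size:
volume ≥ 100 µm³ → lacunar; volume > 300 µm³ or span > 20 µm along an axis
→ vascular (canals are long channels, lacunae compact); everything else,
including thin canaliculi attached to a lacuna, stays canalicular. The
Can.Dn reference volume V_ROI excludes lacunar and vascular voxels only.

Calcein bands are thresholded (Otsu), the two largest components kept, and
each band's surface fitted as the intensity-weighted transcortical centroid
per (longitudinal, depth) column, Gaussian-smoothed; missing columns are
filled from their nearest neighbours. Fewer than two detectable bands is an
error naming what is missing.

## Network extraction (`netextract`)

Thinning uses 3D topology-preserving parallel thinning (Lee's algorithm via
scikit-image); one- and two-voxel debris components that the thinning would
erase are re-seeded so the connected-component count is exactly preserved.
Skeleton voxels are classified by 26-neighbour count (1 end, 2 chain, ≥3
branch). Adjacent branch voxels merge into one junction node at their
centroid (merge radius 1 voxel — see the note below). Skeleton voxels
within 2 voxels of a lacunar component anchor their chain to that lacuna's
node, placed at the component centroid; the chain's *geometry* still ends at
the lacunar surface, so Can.Ln measures the canaliculus, not a virtual
segment through the lacuna interior. Pure cycles get one node (kind
"loop") at their lexicographically smallest voxel and a self-edge.

Free chain ends are extended along their local tangent through foreground
voxels the thinning retracted, gated by the Euclidean distance transform:
the walk stops where the clearance drops below that at the chain end, i.e.
at the true axis endpoint rather than inside the tube cap. Free-ending
chains shorter than 1 µm are pruned as thinning artefacts; pass-through
junctions left with degree 2 are spliced, and junctions reduced to degree 1
demoted to endpoints.

Each chain is fitted with an order-3 parametric smoothing spline over the
cumulative chordal parameter (allowed RMS residual 0.2 µm — large enough to
remove voxel staircase, small enough that every chain voxel stays within
half a voxel diagonal of the curve; a digitized quarter-circle's arc length
is recovered within ~1%). Junction chains are extended to the junction
centroid so edge endpoints coincide with node positions. Arc length is
computed by adaptive quadrature of the spline speed.

**Merge radius.** A 2-voxel merge radius percolates at realistic densities:
dilating branch voxels fuses whole junction neighbourhoods into single
high-degree nodes and inflates spline lengths through distant centroids.
With 26-adjacency merging only (radius 1), junction recovery on the
reference phantom is ~95–98% with ~95% of junctions at degree 3.

## Connectomic statistics (`connectomics`)

Two assignment rules coexist deliberately. For *densities*, edges are
resampled into ≤0.1 µm pieces (each original polyline segment subdivided on
its own line, so binned length is conserved to floating point) and each
piece counts toward the sub-volume containing its midpoint — lengths are
clipped across cell boundaries. For *length histograms*, a whole edge is
assigned to the cell containing its centre of mass. Cells are half-open;
samples on the outer domain face fold into the last cell so nothing is
lost. Cells with V_ROI = 0 are dropped from statistics; border cells keep
their actual partial V_ROI.

DoC statistics run over junction nodes only (degree ≥ 3 by definition);
lacunar, endpoint and loop nodes are excluded. The long-canaliculi fraction
is reported both count- and length-weighted; the length-weighted variant is
the default for density–connectivity regressions. Regressions are ordinary
least squares with no weighting; a cell enters the %long fit with ≥1
assigned edge and the %tree fit with ≥1 junction, and fewer than 3 eligible
cells is an error.

Cortical profiles average per-cell densities over the longitudinal and
depth axes per transcortical column, normalize the column position so 0 is
the endosteal and 1 the periosteal edge of the bone mask, resample to a
fixed grid spanning [0, 1], and report the calcein surfaces on the same
axis.

## Known limitations

* Can.Dn recovery on the reference phantom is ~0.90–0.93 of truth: the
  residual deficit is canaliculi running through the detected (slightly
  oversized) lacunar halo, plus smoothing of sub-voxel tortuosity. Both are
  properties any centerline method shares at this resolution.
* At 0.2 µm/µm³ and 303 nm voxels, tube crossings closer than ~1 µm are
  physically unresolvable; the generator avoids them, so recovery numbers
  quantify the pipeline under resolvable geometry only.
* The region mask supports one transcortical axis convention (axis 1);
  rotated acquisitions must be transposed on load.
* Vascular canal detection is a size/extent heuristic, validated only on
  geometric stand-ins.
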