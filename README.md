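# lcnet — connectomics of the osteocyte lacuno-canalicular network

Cortical bone is permeated by the lacuno-canalicular network (LCN):
micrometre-scale pores (lacunae, ~100–250 µm³) housing osteocyte cell bodies,
connected by sub-micrometre channels (canaliculi) carrying their processes.
`lcnet` turns confocal-like 3D image stacks of this porosity
(rhodamine-stained, with calcein labels marking mineralization fronts) into a
spatial network and computes its connectomic statistics:

* **Can.Dn** — canalicular network density, `Can.Dn = Σ Can.Seg_i / V_ROI`
  in µm/µm³, the total canalicular length per unit bone volume with lacunae
  and vascular canals excluded from the reference volume (1 µm/µm³ equals
  10³ km/cm³);
* **Can.Ln** — canalicular length, the arc length of the order-3 spline
  fitted to each network edge; histograms use 1 µm bins and canaliculi
  longer than 5 µm count as "long";
* **DoC** — degree of connectivity of a node; junctions have DoC ≥ 3, and
  DoC = 3 nodes are "tree-like".

The pipeline is: dual-pass adaptive Difference-of-Gaussians binarization
(thin pass for canaliculi, bulky pass for lacunae/vessels) → pore
classification by component volume and extent → topology-preserving 3D
thinning → chain-graph construction → spline fitting. Spatial analyses
partition the volume into cubic sub-volumes (default edge 5 µm, 125 µm³),
map the per-cell density, scan the cell size from 1–20 µm for convergence,
average columns into normalized endosteal→periosteal cortical profiles, and
regress the long-canaliculi and tree-like percentages against the local
density.

Because real LCN stacks are rarely shareable, the package ships a synthetic
phantom generator (`lcnet.synthgen`) that grows ground-truth networks —
ellipsoidal lacunae seeding branching, sterically avoiding random-walk
canaliculi — and renders them into image stacks with PSF blur, depth
attenuation and photon noise. Every stage is validated against this ground
truth.

## Worked example

Run the full pipeline on the reference phantom (a 50 × 50 × 30 µm cortical
volume at a target density of 0.20 µm/µm³, imaged noise-free at 303 nm
in-plane / 270 nm axial voxels):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints

```
seed:                    1
ground-truth Can.Dn:     0.1953 um/um^3
recovered Can.Dn:        0.1810 um/um^3 (181 km/cm^3)
junctions extracted:     1834
tree-like fraction:      0.957
long canaliculi (len):   0.353
```

Reading: the generator hit the 0.20 µm/µm³ target to within its 5% control
band (0.1953); the full image pipeline recovered 93% of that density —
equivalently 181 km of canaliculi in every cm³ of bone. Nearly all
extracted junctions are tree-like (DoC = 3), matching the generated network
in which every branch event creates a degree-3 node, and about a third of
the total canalicular length sits in canaliculi longer than 5 µm.

The same stages are scriptable individually:

```python
from lcnet import (SyntheticSpec, ImagingSpec, generate_network,
                   render_volume, dog_binarize, classify_pores,
                   extract_network, can_dn, subvolume_map)

spec = SyntheticSpec(target_density=0.2, seed=1)
network, truth = generate_network(spec)
image, pores = render_volume(network, truth,
                             ImagingSpec(psf_sigma=(0, 0, 0),
                                         noise_model="none"),
                             canalicular_radius=spec.canalicular_radius)
binary = classify_pores(dog_binarize(image))
extracted = extract_network(binary)
grid = subvolume_map(extracted, domain_size=spec.domain_size)  # 5 um cells
```

or driven from a shell via the `lcnet` command (`simulate`, `segment`,
`extract`, `quantify`, `profile`, `report`, `run`), configured with a YAML
file mirroring `SyntheticSpec` / `ImagingSpec` / stage parameters and a
`--seed` that makes every run reproducible.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` regenerates the reference
phantom from scratch with the given seed, runs segmentation, network
extraction and quantification, prints the recovered density, junction count
and tree-like fraction, and writes the machine-readable result JSON to
`--out`. It touches nothing outside the repository.
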