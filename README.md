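# hearttube

Quantification toolkit for 3D multi-channel fluorescence stacks of a
tubular embryonic heart, validated end-to-end against a synthetic
ground-truth generator. It covers:

- **synthetic generator** (`hearttube.synthetic`) — curved five-compartment
  heart tubes (pre-atrium, atrium, AVC, ventricle, postventricle) with
  wall-resident ellipsoidal nuclei, a thin membrane shell with
  region-dependent intensity, Gaussian PSF blur and Poisson+Gaussian noise;
  every downstream quantity (nucleus volumes, compartment intervals,
  centerline geometry, Golgi offsets) is known analytically.
- **nucleus segmentation** (`hearttube.segmentation`) — anisotropy-aware
  multiscale Laplacian-of-Gaussian blob detection (scale-normalized, γ = 2),
  marker-controlled watershed instance segmentation, and physical-unit
  volume measurement.
- **compartment assignment & statistics** (`hearttube.regions`) — nearest
  arc-length compartment assignment with a lumen-distance cutoff,
  normalization to a control group, geometric nucleus→Golgi polarity calls,
  and group tests (Mann-Whitney with an exact permutation null for small
  samples, unpaired t, Kruskal-Wallis).
- **lumen morphometry** (`hearttube.morphometry`) — isotropic resampling,
  compartment interface centroids, AVC length, a distance-ridge central
  line, and the convolutedness (looping) ratio.
- **membrane line profiles** (`hearttube.profiles`) — surface normals from
  the signed distance field, perpendicular intensity profiles with per-line
  maxima, max-projection ROI readout, and reference normalization.
- **pipeline** (`hearttube.pipeline`) — declarative YAML-configured runs
  (generator → segmentation → assignment → morphometry → profiles →
  statistics) with per-heart failure isolation and bit-reproducible reports.

Conventions: axis order `(z, y, x)`, all physical quantities in µm, voxel
centres at `index × spacing`, compartments labelled 1–5 inflow→outflow.

## CLI

```bash
hearttube synthesize --config synth.yaml --seed 7 --outdir heart0/
hearttube segment-nuclei --image heart0/nuclear.tif --sigmas 1.2,1.6,2.0,2.4 --out seg/
hearttube morphometry --labels heart0/compartments.tif --out morpho.json
hearttube profiles --image heart0/membrane.tif --membrane heart0/membrane_labels.tif \
    --region-labels heart0/compartments.tif --region 3 --n-lines 8 --out prof/
hearttube compare --nuclei a/nuclei.csv b/nuclei.csv --test mann_whitney
hearttube run --config pipeline.yaml          # all stages, one report.json
```

A minimal pipeline config:

```yaml
seed: 3
outdir: run/
hearts:
  - {id: c0, group: control, synthetic: {}}
  - {id: m0, group: mutant, synthetic: {avc_volume_scale: 1.25}}
comparisons:
  - {test: mann_whitney, groups: [control, mutant], reference: control}
```

Images are multi-page TIFFs with a `*.tif.json` spacing sidecar; labels are
integer TIFFs; tabular outputs are CSV and reports JSON.

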