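# junctionmap

Quantification toolkit for two-color super-resolution images of epithelial
apical junctions, plus immunogold electron-microscopy coordinates.  It
implements four analyses around a common idea — use the tight-junction (TJ)
marker as the spatial reference for everything else:

- **Density profiles** (`junctionmap.profiles`): intensity lines sampled
  perpendicular to a traced junction (planar view) or along the apico-basal
  axis, referenced to the TJ marker (sub-pixel peak, or the most apical
  1/3-of-max crossing), normalized per junction, and pooled into mean ± SD
  density curves; planar × apico-basal curves combine into a 2D product map.
- **Protein–protein proximity index** (`junctionmap.proximity`): straight
  junctions are resampled into 400-nm-wide bands centered on the TJ
  reference, concatenated, and auto-/cross-correlated along the junction
  axis.  P1 = C12/A2 and P2 = C12/A1 from the fitted correlation peak
  amplitudes read as the fraction of one protein population in proximity to
  the other (0 = none, 1 = perfect).
- **Immunogold distances** (`junctionmap.em`): signed apico-basal/lateral
  offsets from the TJ, exact point-to-polyline membrane distances,
  compartment classification (microvilli / membrane vicinity / cytoplasm),
  and the fraction of particles within the antibody-linkage distance
  (3–37 nm window; < 38 nm association threshold).
- **Cluster–region contingency** (`junctionmap.clusters`): prominence-based
  cluster detection and counts of cluster centroids per annotated
  microvilli region.

A fully ground-truthed synthetic scene generator
(`junctionmap.synthetic`) renders TJ lines, Gaussian protein clusters with
a Gaussian PSF (analytic convolution), Poisson noise, controllable
channel-overlap fractions, and gold-particle sets with known membrane
distances — so every stage is testable without microscopy data.

## CLI

All stages run through one entry point and write a machine-readable
manifest (inputs, config hash, versions, seed) next to their outputs:

```sh
junctionmap simulate --out sim/ --seed 1 --offset-mean 200 --offset-sd 30
junctionmap profile --images sim/channel_ref.tif --images sim/channel_target.tif \
    --traces sim/traces.csv --orientation planar --out prof/
junctionmap ppi --images ref.tif --images target.tif --traces traces.csv \
    --band-width 400 --out ppi.json
junctionmap emdist --particles p.csv --membrane m.csv --tj-ref 0,0 \
    --apical-axis 0,1 --out em/
junctionmap microvilli --image c.tif --regions r.csv --out mv/
```

Shared constants (pixel size, band width, normalization mode, EM
thresholds, …) live in a YAML config (`--config cfg.yaml`); flags override
config values.  Traces are CSV polylines in px
(`junction_id,vertex_index,x_px,y_px[,apical_dx,apical_dy]`); EM inputs
are CSV in nm.

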