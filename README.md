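# isletradius

Semi-automated quantification of **endocrine cell localization and
distribution in pancreatic islets** from stained section images.

Rodent islets of Langerhans normally show a mantle–core architecture: a
central core of insulin-producing beta cells wrapped by a mantle of
glucagon-producing alpha cells and somatostatin-producing delta cells. In
metabolic disease (impaired glucose tolerance, diabetes, some gestational
states) this arrangement remodels, with alpha and delta cells drifting toward
the islet center. `isletradius` turns that qualitative observation into a
per-islet number that can be compared statistically across animals, strains
and conditions.

## The statistic

For each hormone-positive pixel *p* inside a user-supplied islet boundary
polygon, the **relative radius** is

```
rel_radius(p) = 100 · r(p) / r_boundary(θ(p))      [%]
```

where `(θ, r)` are the polar coordinates of the pixel about the polygon
center (arithmetic mean of the vertices by default) and `r_boundary(θ)` is
the boundary radius in the same direction, obtained by **linear interpolation
of vertex radius as a function of vertex angle**, with circular wraparound.
A value near 0 means the cell sits at the islet center; near 100, at the
mantle. The per-islet summary is the arithmetic mean over all pixel radii
≤ 100 % (values above 100 % can arise after repairing an invalid polygon and
are excluded, with the excluded percentage reported), alongside the
**relative area** — the percentage of islet raster pixels that are
hormone-positive.

A boundary polygon is *valid* when its vertex angles about the center are
weakly monotonic up to one cyclic wraparound (every convex polygon is valid,
for any start vertex and either orientation). Invalid polygons are
automatically repaired by sorting the vertices by angle; the repair is
flagged in the results because it alters the analyzed shape.

Hormone-positive pixels come from pure thresholding: an HSV color box for
DAB-brown immunohistochemistry (IHC), or an intensity threshold (fixed or
per-image Otsu) for grayscale immunofluorescence (IF). DAPI support images in
a `support/` subfolder (matched by the first three filename characters) are
contrast-stretched for display only and never influence the computation.

## Worked example

Simulate three synthetic IHC islets with a peripheral ("mantle") cell
placement — cells at 85–95 % of the boundary radius — then analyze them:

```bash
$ isletradius simulate --phenotype mantle --n 3 --mode ihc --seed 7 --out demo/mantle
wrote 3 mantle islet(s) to demo/mantle (mean intended fraction 0.900)
$ isletradius analyze demo/mantle --mode ihc --out demo/results
wrote demo/results.csv and demo/results.xlsx (3 islet rows)
$ cat demo/results.csv
image_id,islet_id,stain_mode,n_cell_pixels,n_islet_pixels,relative_area_pct,mean_relative_radius_pct,n_included,n_excluded,pct_excluded,polygon_was_invalid,excluded_no_staining
000_islet.png,1,ihc,482,20072,2.401355,89.772251,482,0,0.000000,False,False
001_islet.png,1,ihc,465,20072,2.316660,90.089077,465,0,0.000000,False,False
002_islet.png,1,ihc,454,20072,2.261857,90.050780,454,0,0.000000,False,False
```

Each row is one islet: 454–482 brown pixels were detected inside a boundary
of 20 072 raster pixels (relative area ≈ 2.3–2.4 %), and their mean relative
radius is ≈ 90 % — recovering the intended placement at 90 % of the boundary
radius. No radii exceeded 100 % and no polygon needed repair. Real data work
the same way: drop TIFF/JPG/PNG images plus one `<image>.polygons.json`
sidecar per image (`{"image": ..., "islets": [{"id": ..., "vertices":
[[x, y], ...]}]}`) into a folder and run `isletradius analyze`. Detection
thresholds live in a TOML file passed via `--config`:

```toml
[ihc]
hue = [0.0, 50.0]        # degrees; may wrap through 0
saturation = [0.2, 1.0]
value = [0.1, 0.95]

[if]
threshold = "otsu"       # or a fixed intensity in [0, 1]
```

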