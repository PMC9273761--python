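# vasctree

Topological and geometrical analysis of the retinal vascular tree from 2-D
colour fundus photographs and their vessel segmentations.

Retinal vessel calibre, branching geometry, tortuosity and fractal
complexity are established biomarkers for diabetic retinopathy,
hypertensive retinopathy and related vascular disease.  Extracting them
reliably requires more than a binary vessel mask: the mask must be reduced
to 1-px centrelines, organised into a vascular graph, tracked into rooted
arterial/venous trees, and screened for the annotation and topology errors
that silently corrupt every downstream measurement.  `vasctree` implements
that whole chain for people building or validating vessel segmentation
datasets and vascular-biomarker pipelines:

- **Preprocessing** — FOV detection, crop/resize to the 1024×1024 working
  convention (aspect ratio of the FOV preserved, exact inverse recorded),
  CLAHE and local contrast enhancement, Soares-style FOV border extension,
  and Sauvola local adaptive binarization of soft vessel predictions
  `t(x) = m(x)·(1 + k·(s(x)/R − 1))`.
- **Skeleton & graph** — spur-free Lee skeletonization; landmark pixels by
  8-neighbour count (terminal = 1, bifurcation ≥ 3); skeleton segments as
  graph edges; region-growing tree tracking from starting vertices near the
  optic disc; Strahler stream orders (leaf edges 1, order *k*+1 where two
  order-*k* children meet).
- **Abnormality screening** — a healthy A/V tree is a rooted binary tree:
  vertices with > 3 connected edges (merged bifurcations) and graph circles
  (an edge of a tracked tree absent from its own minimum spanning tree) are
  flagged; geometrical rules flag focal calibre variation > 3 px, parent
  calibre below child calibre, bifurcation angle > 150°, and vessel
  tortuosity index > 5; segments with mean calibre > 5 px are thick.
- **Annotation QC** — interior holes by flood fill (per artery/vein mask),
  isolated components below 100 px, manual-vs-predicted label
  disambiguation into *unlabelled* and *mislabelled* pixels, and 128×128
  patch grids for subjective quality scoring (score-0 patches excluded).
- **Measurements** — per-centreline-pixel diameters (2·EDT − 1),
  bifurcation angles in a 10-px search radius, Khansari-style tortuosity
  index, box-counting fractal dimension over the FOV and the standardized
  macula disk (radius 0.6× the macula–disc distance), and FOV-restricted
  segmentation metrics (Dice = F1, AUPR, accuracy/sensitivity/specificity).
- **Synthetic fixtures** — tree-shaped masks rendered as envelopes of disks
  with exact ground truth (calibres 1–20 px, controlled angles and
  tortuosity) plus injectable defects (loops, holes, small components,
  near-coincident bifurcations, border spurs), so the whole chain is
  testable without any dataset download.

## Worked example

Generate a synthetic depth-3 vascular tree and run the full analysis:

```sh
vasctree synth --seed 7 --out-dir fix
vasctree run --mask fix/vessel.png --fov fix/mask.png \
             --od 60,256 --od-radius 20 --out-dir reports
```

which prints (configuration echo omitted):

```json
{
 "vasctree_version": "0.1.0",
 "n_vertices": 8,
 "n_edges": 7,
 "n_trees": 1,
 "n_orphan_vertices": 0,
 "n_overdegree_vertices": 0,
 "n_cycles": 0,
 "n_geometry_flags": 0,
 "n_holes": 0,
 "n_small_components": 0,
 "fd_fov": 1.4407359264302027
}
```

Read: the mask yielded one tracked tree whose 8 vertices and 7 edges
satisfy the binary-tree identity |E| = |V| − 1 (3 bifurcations, 4 ending
vertices, 1 starting vertex at the optic-disc rim); no topological or
geometrical rule fired and the QC scans found no holes or stray
components, as expected for a clean fixture; the box-counting fractal
dimension of this sparse synthetic tree is 1.44, between a curve (1) and a
space-filling region (2).  `reports/` additionally holds the graph
(JSON + GraphML with pixel paths), the per-segment table
(`segments.csv`: length, mean diameter, Strahler order, thick/thin) and
the individual topology/geometry/QC/fractal reports.

Injecting a defect changes exactly the reports that should notice it, e.g.
`vasctree synth --seed 7 --defect loop --out-dir fix2` produces a mask
whose topology report contains one graph circle.

All thresholds (3 px, 150°, VTI 5, 5 px thick/thin, 100 px components,
10 px angle radius, 0.6 macula factor, 128 px patches, 1024 working
dimension) live in one YAML configuration; `vasctree config` prints the
full default set.

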