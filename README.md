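# fishcount

Cell type-resolved quantification of single-molecule RNA transcripts from
multi-channel 3D fluorescence microscopy stacks.

In single-molecule FISH (smFISH) and RNAscope experiments each transcript
appears as a diffraction-limited fluorescent spot. Combining a transcript
channel with a nuclear counterstain (DAPI) and immunofluorescence
cell-marker channels (e.g. GFAP for radial glia, SATB2 for excitatory
neurons) allows transcript counts to be attributed to individual nuclei
*and* to cell types — e.g. showing that *HES1* is expressed only in
GFAP-positive cells while *BCL11A* is expressed in both cell classes.
`fishcount` is the analysis half of such an experiment: from raw z-stacks
to a per-nucleus, per-cell-type transcript count table.

## Method

For one field of view with channels $I_c(z, y, x)$ the pipeline runs:

1. **Normalization** — per-channel min–max rescale to $[0,1]$.
2. **Band-pass filtering** of transcript channels:
   $F = G_{\sigma_\ell} * \max(I - G_{\sigma_h} * I,\, 0)$, a Gaussian
   high pass (background removal, $\sigma_h = 10$ voxels) followed by a
   Gaussian low pass (spot-scale smoothing, $\sigma_\ell = 1$).
3. **Spot detection** — local maxima above a percentile floor, refined to
   subpixel precision by least-squares 3D Gaussian fitting (centroid
   fallback); each candidate's *mass* is its integrated window intensity
   $m = \sum_{w} F$, and only spots with $m \ge$ `min_mass` survive, with
   a minimum center separation keeping the higher-mass spot. An interval
   report bins spots around user-chosen mass bounds and renders them
   color-coded over the filtered image so `min_mass` can be chosen by eye.
4. **Nuclei segmentation** — watershed on the negated smoothed DAPI
   projection, followed by depth-controlled basin merging: two adjacent
   basins $A, B$ with saddle value $s_{AB}$ merge while
   $\mathrm{depth}(A,B) = s_{AB} - \max(\min_A, \min_B) <$ `min_depth`
   (equivalent to h-minima dynamics). Small `min_depth` ($10^{-6}$–$10^{-7}$)
   suppresses over-segmentation; deliberately larger values
   ($5\times10^{-6}$–$5\times10^{-5}$) split touching nuclei at their
   shallow border saddle. A `min_size` filter removes debris, and
   remaining errors are fixed declaratively by region ID
   (merge `[[3,4]]`, delete `[2]`).
5. **Cell-type assignment** — each marker projection is thresholded into a
   positivity mask; a nucleus is marker-positive when
   $|N \cap M| / |N| \ge$ `min_overlap_fraction`.
6. **Counting** — nascent mode looks each spot's $(y,x)$ up in the nucleus
   label map; mature mode first expands nuclei into disjoint cell
   territories inside the marker mask. Background spots are reported,
   never dropped: $\sum_k n_k + n_{bg} = n_{total}$ always.

Every run writes per-sample tables (`spots.csv`, `regions.csv`,
`assignments.csv`), a label map, five per-step QC images plus a composite,
a metadata file that re-establishes the run bit-for-bit, and appends to
cumulative batch results (CSV + XLSX).

## Worked example

No real data is needed — the package ships a synthetic-experiment
generator with full ground truth:

```sh
fishcount simulate --config fixture.yaml --out demo/ --seed 9
fishcount run --config run.yaml
fishcount report --batch demo_out/results.csv
```

or in Python:

```python
from fishcount import (FixtureParams, generate_experiment, RunConfig,
                       DetectionParams, AssignmentParams, run)
from fishcount.synth_fixtures import expected_spot_mass, score_against_truth

exp, truth = generate_experiment(FixtureParams(seed=7))   # 6 nuclei, 2 cell types
min_mass = 0.5 * expected_spot_mass(0.5, (1.0, 1.5, 1.5), 3)
cfg = RunConfig(out_dir="demo_out",
                detect=DetectionParams(min_mass=min_mass, separation=2.0,
                                       percentile_floor=99.5),
                assign=AssignmentParams(marker_threshold={"GFP": 0.3,
                                                          "mCherry": 0.3}))
res = run(cfg, experiment=exp)
print(res.assignments[["nucleus_id", "cell_type", "count_HES1"]])
print(score_against_truth(res.spots["HES1"], res.labels, res.assignments, truth))
```

prints

```
   nucleus_id cell_type  count_HES1
0           1       GFP          12
1           2       GFP           8
2           3   mCherry           2
3           4       GFP          10
4           5   mCherry           1
5           6   mCherry           2
{'recall': 1.0, 'precision': 1.0, 'rmse': 0.1099..., 'n_matched': 35,
 'region_count_error': 0, 'mean_iou': 0.9285..., 'matched_regions': 6,
 'assignment_accuracy': 1.0, 'total_count_error': 0}
```

i.e. all 35 simulated transcripts were detected (no false positives) with
~0.1 voxel localization error, all 6 nuclei were segmented and typed
correctly, and each nucleus's count matches the generating ground truth.
(The GFP nuclei were drawn from a Poisson with mean 8, the mCherry nuclei
from mean 2.)

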