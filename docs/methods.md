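# Methods

This note documents the models, parameter choices and numerical decisions
behind `fishcount`, and what the synthetic test conditions do and do not
establish about real microscopy data.

## Image model and normalization

Stacks are held as `(z, y, x)` arrays, origin top-left, 0-based indices;
anisotropic voxel sizes (default 0.4 µm z-step, 0.285 µm in-plane) are
carried as metadata only — every length parameter in the pipeline is in
voxel units, because the algorithms operate on grids, not physical space.

Channels are normalized by a per-channel min–max map to $[0,1]$ (constant
channels map to zero). Min–max rather than percentile scaling was chosen
so that intensity-scale parameters — the spot mass gate and especially the
basin-merge depth, whose useful magnitudes are $10^{-7}$–$10^{-4}$ — act
on a fixed, interpretable scale. Percentile clipping is available as an
option but off by default, since clipping would distort the very saddle
depths `min_depth` measures. This normalization is a config-visible
choice, not a claim about the acquisition.

## Band-pass filtering

Transcript channels are filtered with a Gaussian pair: subtract a wide
blur (high pass) and smooth with a narrow one (low pass). Defaults
`sigma_high = 10`, `sigma_low = 1` voxels, `truncate = 4`: spot FWHM is
2–3 px at 0.285 µm pixels, while autofluorescent background varies at
cell scale (tens of px). Filtering is 3D with isotropic sigma in voxel
units (per-axis override available), boundary mode `reflect`. Negative
values after the high pass are clipped to zero so integrated spot masses
are non-negative; the clip only engages where the local mean exceeds the
signal, i.e. outside spots, so it does not bias spot photometry.

## Spot detection

Candidates are local maxima above the `percentile_floor`-th intensity
percentile. Each candidate window — half-size `spot_radius` per axis,
clamped at borders and on degenerate axes (a z=1 stack is handled as
purely 2D) — is summed to give the spot *mass*; candidates below
`min_mass` are discarded before any fitting, which the result does not
depend on (mass is fit-independent) but which avoids fitting noise peaks.
Surviving candidates are refined by least-squares Gaussian fitting
(amplitude, offset, center, per-axis sigma; bounds keep sigma in
$[0.1, 4r]$; at most 100 function evaluations). A fit that fails to
converge or lands outside sigma $[0.5, 2r]$ falls back to the
intensity-weighted centroid and is flagged in the `fallback` column.

Mass is defined as the window sum of filtered intensities — integrated
intensity is robust to peak-sampling jitter, and it is the quantity the
gate name `min_mass` conventionally refers to in diffraction-limited
particle locators. Whether a user-supplied intensity bound refers to peak
or integrated brightness is therefore resolved here as: both the gate and
the interval-report bounds are on the mass scale.

Minimum-separation suppression is greedy in decreasing mass order, ties
broken by $(z, y, x)$ lexicographic order for determinism. This makes the
retained set at threshold $T$ exactly the threshold-0 set filtered to
mass $\ge T$ — the count is non-increasing in `min_mass` and threshold 0
dominates every other threshold, which the tests assert structurally.

Default interval-report bounds are $(0.8, 1.2) \times$ `min_mass`, so the
QC overlay shows precisely the spots near the gate.

## Nuclei segmentation and depth-controlled merging

Segmentation is 2D on the max-projected DAPI channel: smooth
(`smoothing_sigma`, default 2 px), threshold (Otsu by default — the
binarization rule is otherwise unconstrained — or fixed), then watershed
on the *negated* smoothed intensity restricted to foreground, seeded from
every regional minimum of that surface. Deliberately, no peak-distance
seeding is used: `min_depth` is the sole control of over- versus
under-segmentation.

The merge criterion: for adjacent basins $A, B$ with saddle
$s_{AB} = \min_{\text{boundary pairs}} \max(f_p, f_q)$,

$$\mathrm{depth}(A,B) = s_{AB} - \max(\min_A, \min_B),$$

and pairs merge smallest-depth-first (priority queue, stale entries
re-keyed exactly; ties broken by smaller label pair) while depth <
`min_depth`. This equals the h-minima *dynamics* criterion, so the
classical h-minima-suppressed watershed serves as an independent oracle:
on random smooth surfaces the partitions agree exactly for the advisory
depth range ($10^{-6}$–$10^{-4}$). At much larger depths ($\gtrsim
10^{-3}$) re-flooding the reconstructed surface can route a few boundary
pixels differently through filled plateaus; region counts still agree.
All 2D morphology uses 4-connectivity consistently (the h-minima oracle
is given a matching footprint, since its library default is
8-connectivity).

Because the surface is negated normalized intensity, `min_depth` is in
normalized intensity units: values around $10^{-6}$–$10^{-7}$ suppress
spurious splits, and $5\times10^{-6}$–$5\times10^{-5}$ split
under-segmented touching mammalian nuclei, to be tidied afterwards by
ID-based correction. A distance-transform surface is available as an
option (`seg.surface = distance`), with `min_depth` then in pixels.

`min_size` (default 50 px) removes small artifacts such as pyknotic
nuclei. Correction is declarative: merge sets keep the lowest ID, deleted
regions become background, labels are compacted, and the edit list is
stored in the run metadata as an audit record. Correction is batch (ID
lists in config/CLI), not interactive.

## Assignment and counting

Marker channels are max-projected, smoothed and thresholded; components
smaller than the region-size floor are dropped. A nucleus is positive for
a marker when at least `min_overlap_fraction` (default 0.5 — majority
overlap, the least surprising rule where only a brightness threshold is
otherwise specified) of its area lies in the mask. Multi-positive nuclei
are reported as such rather than resolved: the markers modeled are
mutually exclusive and no tie rule is defined for them. Nuclei positive
for nothing are retained as `unassigned`.

Nascent transcripts sit at their gene locus in the nucleus, so nascent
mode assigns each spot to the nucleus label under its $(y,x)$; spot z is
ignored because segmentation is 2D. Mature mRNA fills the cytoplasm, so
mature mode first partitions the marker mask into per-cell territories by
multi-source geodesic BFS from the nucleus regions (4-connectivity, ties
to the lower nucleus ID — implemented directly so the nearest-seed oracle
equality in the tests is exact including tie pixels; a nucleus outside
the mask keeps its own mask). Counting is conservative by construction:
background spots are tallied, never dropped. Mature mode deliberately
avoids segmenting the cytoplasm channel itself — 2D segmentation of
overlapping cell bodies is unreliable — and instead derives territories
from the trusted nucleus segmentation expanded into the marker mask.

## Synthetic experiments

The generator renders what the pipeline expects to see, with every latent
variable known:

* **Nuclei**: smooth Gaussian blobs (σ = r/2, slight anisotropy) extruded
  over z with a profile whose maximum slice weight is exactly 1, so the
  projection reproduces the 2D render bit-for-bit. Rendered noise-free:
  nuclear counterstains are far brighter than background, and the
  segmentation tests target saddle geometry, not noise robustness.
* **Touching pairs**: a separable ridge profile with grid-aligned peaks
  of value exactly $A$ and a cosine dip to exactly $A - d$ at the
  midpoint. Pairs render at the image maximum, so after normalization the
  saddle depth equals the requested $d$ to float precision — this is what
  makes the `min_depth` transition testable at $d = 10^{-5}$ with ±10%
  margins.
* **Markers**: bright disks over their cell type's nuclei (amplitude 0.8)
  plus Gaussian noise.
* **Transcripts**: per-nucleus counts drawn Poisson with the cell type's
  mean (the standard two-type condition uses means 8 and 2 across 3+3
  nuclei), placed uniformly in the nucleus core (blob ≥ 0.7 of its peak,
  where any reasonable foreground threshold keeps the pixel) with a
  minimum 3D separation of 6 voxels ≈ 3.3σ of the effective
  PSF-plus-smoothing width, rendered as Gaussian PSF spots (σ = 1.5
  voxels in-plane, 1.0 in z, approximating the 0.285 µm pixel / 0.4 µm
  z-step optics ratio; peak 0.5) over a smooth background gradient with
  additive Gaussian noise (σ = 0.01, peak SNR 50).

Standard problem sizes: the two-type experiment is a 24×320×320 stack
with 6 nuclei of radius 16–20 px; the detection benchmark is 100 spots in
a 16×160×160 volume; the merge-oracle surfaces are 32×32. These sizes
keep every acceptance quantity computable in seconds while leaving each
effect (saddle depths, spot separations, Poisson statistics) fully
expressed.

What passing does *not* show: robustness to overlapping nuclei in z, to
spot densities where PSFs blend (separations below ~2× the effective PSF
width), to non-Gaussian camera noise, chromatic shifts, or uneven
illumination beyond a smooth gradient. The detector's default `min_mass`
guidance (`0.5 × expected_spot_mass(peak, psf, r)`, the analytic window
integral of the model PSF) assumes roughly uniform spot brightness; real
data with dim spots needs the interval-report overlay to choose the gate.

## Determinism and reproducibility

Every stage is a pure function of its inputs and parameters; no stage
uses randomness. QC images are rendered with fixed palettes and fonts and
are byte-identical across re-runs; batch spreadsheets carry fixed
timestamps. Run metadata records every parameter of every stage plus the
manifest and edits; re-running from a loaded metadata file reproduces
`spots.csv`, `assignments.csv` and the batch rows bit-for-bit. Stage
artifacts are cached by content hash of upstream data plus parameters, so
changing a downstream parameter re-runs only downstream stages.

## Known limitations

* Segmentation is 2D; transcripts in nuclei overlapping along z cannot be
  correctly apportioned.
* The Gaussian fit assumes an isolated spot in its window; in dense
  clusters masses are inflated by neighbors and the centroid fallback
  rate rises.
* Territory expansion is geodesic within the thresholded marker mask; it
  does not model cell morphology beyond that mask.
* Batch parallelism is by independent processes per sample; the batch
  writer's conflict guard serializes appends but is not a database.
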