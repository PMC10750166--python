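# Methods

## Pipeline model

The pipeline treats segmentation as a physical-units problem. Distal
germline nuclei in early meiotic prophase are close to spherical with a
diameter near 3.5 µm, but their chromatin staining is discontinuous:
paired, partially condensed chromosomes produce bright foci separated by
dark nucleoplasm, so intensity alone under-segments or fragments nuclei.
The pipeline therefore (a) normalizes geometry before detection and (b)
blurs away the intranuclear texture.

**Rescaling.** The lateral scale factor is `s = 30 · p / d` for pixel size
`p` (µm/px) and expected diameter `d` (µm), so the rescaled pixel size is
`d / 30` and one nucleus spans 30 px — the object size blob detectors and
the Cellpose family are tuned for. At the reference calibration
(p = 0.117 µm/px, d = 3.5 µm) the factor is ≈ 1.003. Rescaling is
lateral-only (first-order interpolation); the z axis is never resampled.
Instead the anisotropy `a = Δz / (d/30)` is handed to the backend, which
mirrors how 3D inference engines consume z-step metadata and avoids
inventing z-planes.

**Blurring.** `blurfactor` is interpreted as the Gaussian standard
deviation in rescaled pixels (the knob's unit is otherwise undefined); the
axial sigma is `blurfactor / a`, making the kernel spherical in µm. The
blur is applied in 3D rather than per-slice: a physically isotropic kernel
is the natural reading of a pipeline that is otherwise strictly
physical-units, and per-slice blurring would leave axial texture
untouched. Default 2.5 for chromatin staining, 3.5 for deconvolved or
synaptonemal-complex images; 0 disables it.

## Baseline backend

The classical baseline exists so the pipeline is correct and testable
independently of any trained network. It is fully deterministic:

1. Foreground mask: Otsu's threshold on the blurred volume.
2. Seeds: local maxima of the scale-normalized, anisotropy-aware negated
   Laplacian of Gaussian at lateral sigma `30 / (2√3)` ≈ 8.7 px (the
   matched-filter scale for a 30 px ball), restricted to the foreground,
   with an ellipsoidal exclusion footprint of lateral radius 13.5 px and
   axial radius 13.5/a, so at most one seed survives per nucleus-sized
   region.
3. Marker-controlled watershed on the inverted smoothed intensity inside
   the foreground mask; instances are 6-connected by construction.

`cellprob_threshold` has a documented meaning only for Cellpose, where it
gates the predicted cell probability. The baseline maps it onto its own
detection stringency: a seed must exceed `0.1 · max(response) · 2^t`.
At the default `t = 0` every seed with at least a tenth of the strongest
blob response is kept; raising `t` monotonically removes seeds, matching
the knob's direction in Cellpose. The constants are a design choice, not a
claim of equivalence.

The Cellpose adapter forwards the preprocessed volume, anisotropy and
`cellprob_threshold` verbatim, exposes 3D-vs-stitching as an option, and
raises a capability error when the optional dependency or weights are
absent — it never falls back silently.

## Post-filters

`clean_borders` deletes an instance iff it touches slice 0 or Z−1, or has
a voxel with lateral index < 2 or ≥ dim−2. The asymmetry (touch in z,
2-px margin in xy) is deliberate and preserved exactly; the operation is
idempotent and never edits surviving voxels. The shape filters measure
size as voxel count, solidity as voxels over 3D convex-hull voxels
(degenerate hulls — single voxels, coplanar objects — default to 1),
z-thickness as the number of distinct occupied slices, and elongation as
the ratio of extreme principal-axis lengths of the voxel cloud in
physical µm, with a half-voxel variance floor so one-slice objects get a
finite, honest axial extent. Measuring elongation in µm rather than voxels
keeps a 2.6× anisotropy from masquerading as 2.6× elongation.

## Evaluation

Instances are matched one-to-one among pairs with IoU strictly above the
threshold (default 0.5, overridable), maximizing pair count and then total
IoU via linear assignment; the Jaccard index is `TP / (TP + FP + FN)` and
1.0 for two empty volumes. Above threshold 0.5 a voxel set can exceed 0.5
IoU with at most one partner, so maximum-cardinality and greedy matching
coincide; the assignment formulation is kept because the threshold is
user-adjustable below 0.5. The test suite checks the matcher against
exhaustive enumeration of all one-to-one matchings for up to 6 instances
per side. Scores are aggregated per image (mean ± sd, median, IQR), not by
pooling instances across images, matching how per-image box plots are
drawn.

## Ground-truth preparation

Orthogonal xz/yz views are resampled along z by the stack anisotropy
(linear for intensity, nearest for labels) so a view pixel equals the
lateral pixel size; xy views pass through. The train/test split takes
`round(f · N)` items for the test set (120 views at f = 0.1 give 108/12),
shuffled by a seeded generator.

Augmentation draws, per variant: horizontal/vertical mirroring (p = 0.5
each), a rotation angle uniform in [0, 90]°, a relative noise sigma in
[0, 0.10] of the image sd (additive Gaussian), a multiplicative intensity
factor in [0.7, 1.3] followed by min–max renormalization to the original
range, and a blur sigma in [0, 3.5] px. Geometry is applied identically to
image (linear, symmetric padding, shape-preserving) and mask (nearest);
photometric transforms touch the image only. Mask fragments under 9 px
created by edge resampling are dropped, in the spirit of a minimum-mask
training filter. The noise and intensity ranges are this package's
conservative defaults — the protocol names the transforms but not their
parameters — and every sampled value is recorded in the output manifest.
Each view owns an RNG substream keyed on (seed, view index), so outputs
are bit-reproducible and insensitive to reordering. The network training
hyperparameters (500 epochs, momentum 0.9, weight decay 1e-5, learning
rate 0.05, min 2 masks/image) are embedded in the manifest for provenance;
training itself is out of scope.

## Synthetic scenes

The generator emulates the distal-germline regime: spheres with diameter
N(3.5, 0.25²) µm placed by dart-throwing with a center-to-center exclusion
of touching + 0.3 µm (capped at 10⁴ attempts per nucleus, after which it
fails loudly with the attempted volume fraction), kept one voxel clear of
the stack borders. Ground-truth labels are the full spheres — annotators
outline whole nuclei, not chromatin. Intensity is a dim nucleoplasm fill
(0.35) plus ~14 bright foci of 0.9 µm per nucleus (discontinuous
chromatin), convolved with a 0.15 µm-sigma Gaussian PSF stand-in, on a
0.05 background, with Poisson shot noise (scale 200 counts per intensity
unit) and Gaussian read noise (sd 0.02). Geometry lives in physical µm and
is rasterized onto the anisotropic grid (0.117 µm/px, 0.3 µm z-step by
default), so one spec serves any calibration. The default scene is
64×256×256 voxels with 20 nuclei, sized so full-pipeline runs stay well
under a minute.

What the generator does **not** emulate: gonad-scale tissue curvature and
crowding gradients, nucleoli, real PSF side lobes and depth-dependent
aberrations, bleaching, or the appearance differences between AiryScan,
SoRa and deconvolved widefield data. Passing the end-to-end tests
therefore demonstrates that the pipeline's plumbing, units handling,
matching and filters are correct — not that the baseline backend matches
trained-model accuracy on real micrographs.

`corrupt_labels` manufactures predictions with an exactly predictable
error budget: dropping k instances adds k false negatives; splitting an
instance across its centroid adds one FN and two FPs because both halves
are held at or below 0.5 IoU with the parent (for odd voxel counts one
mid-plane voxel is deleted from the prediction so neither half exceeds
half the parent volume). Ten nuclei with 2 dropped score exactly 0.8;
with 1 split, exactly 0.75.

## Numerical choices and edge cases

- Lateral rescaling uses `scipy.ndimage.zoom` with `grid_mode=True` and
  zoom factors chosen to hit the rounded output shape exactly; outputs are
  clipped at 0 and an output dimension below 4 px is an error.
- Blur uses reflective boundaries; total intensity is conserved to 0.1%
  away from borders.
- Labels are mapped back to the acquisition grid by nearest-neighbor on
  the instance map, so users quantify in their original coordinates.
- TIFF resolution tags are trusted only inside 0.01–10 µm/px (a 72-dpi
  stamp is not a calibration); otherwise a YAML sidecar or an explicit
  metadata argument supplies voxel sizes. Non-square pixels are an error,
  never averaged.
- Matching ties (equal-IoU alternatives) are reported sorted by
  descending IoU, then ascending ids, making reports deterministic.

## Known limitations

- The baseline assumes bright, blob-like, roughly equal-sized nuclei; it
  will under-segment touching nuclei whose shared boundary is brighter
  than their cores, and it has no learned shape prior.
- `cellprob_threshold` in the baseline is a documented analogue, not a
  calibration against Cellpose probabilities.
- Border detection of transposed stacks is impossible from pixels alone;
  the (z, y, x) page order is a contract with the caller.
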