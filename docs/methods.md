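# Methods

`pelviseg` implements 3D multi-organ semantic segmentation of female-pelvis
MRI for cervical-cancer radiotherapy planning: the target structures are the
bladder, the merged cervix + gross tumour volume + uterus (CGU) and the
rectum, all organs that are single connected volumes occupying stereotyped
positions in the pelvis. This note records the models, the conventions, and
the design choices made where the design was genuinely open.

## Loss functions

**Dice loss.** `D = 1 - 2*sum(p*q) / (sum(p^2) + sum(q^2))`, with `p` the
one-hot ground truth and `q` the softmax prediction, sums taken jointly over
voxels and channels. The background channel can be excluded from the sums
(`exclude_background`); training defaults to excluding it because at desk
scale background occupies ~95% of the volume and the all-background
prediction is otherwise a near-optimum that flattens early gradients. The
empty-vs-empty case is defined as loss 0 (an absent structure perfectly
predicted).

**Bounding-box loss.** Each foreground channel is projected onto each axis
(sum over the two orthogonal axes, binarised `>0 -> 1`), giving the axis
extent of the structure. The loss is the per-axis L1 mismatch between the
truth and prediction profiles, normalised by the union extent
`R_x + R_y + R_z`, then averaged over foreground channels. Reading the
profile difference element-wise (positions covered by exactly one mask)
rather than as a difference of counts penalises displaced-but-equal-extent
footprints; both readings coincide on nested masks. A channel empty in both
volumes contributes 0. The term is bounded in [0, 1], symmetric on crisp
input, and zero for any prediction whose per-axis footprint matches the
truth.

**Positional Dice loss (PDL).** The sum of the two, in [0, 2]. The
bounding-box term targets segmentation noise — detached false-positive blobs
far from the organ move the predicted footprint strongly while barely moving
the overlap term.

**Dice + cross-entropy (DCE).** The Dice loss plus mean voxelwise
categorical cross-entropy with predictions clipped at 1e-7; included as the
customary baseline combination.

**Differentiable forms.** The projection binarisation is replaced during
training by the saturated sum `min(sum, 1)`: exact on binary input, with a
subgradient almost everywhere. All losses exist in one code path that runs
either on plain arrays (crisp evaluation, float64) or on autodiff tensors
(training, float32); analytic gradients are verified against central finite
differences to 1e-4 in the test suite.

## Network architectures

All three networks share a 3D encoder-decoder backbone with four encoder
resolutions (three downsamplings), filter counts `F, 2F, 4F, 8F`:

* standard convolution block = 3x3x3 convolution, instance normalisation
  (learned affine), dropout 0.2, ReLU; two blocks per level by default
  (configurable — the count is an open choice);
* downsampling by stride-2 convolutions (no max-pooling); skip connections
  are additive (not concatenated); reconstruction stage = kernel-2 stride-2
  transposed convolution, skip addition, two standard blocks;
* head = 1x1x1 convolution to the class count with per-voxel softmax.

**M-Net** adds a second input: the per-case binary class vector broadcast to
a constant `(X,Y,Z,C)` volume, passed through a convolution + factor-2
average-pooling chain producing one tensor per encoder resolution, each
added elementwise to that level's feature map after its convolutions. The
vector encodes gross anatomical regime (inflated bladder, tumour-dominant
CGU) and acts as a learned mask conditioning the encoder.

**DM-Net** additionally inserts, between the encoder's deepest level and the
decoder, three dilated convolution blocks (instance norm + leaky-ReLU, no
dropout) with equal dilation rates and decreasing filters `4F, 2F, F`,
followed by one standard block. Consecutive equal-rate dilations grow the
receptive field while limiting gridding artefacts. The dilation rate is 2
(the value is an open choice; only "equal" is fixed), leaky slope 0.01.
Because the dilated chain is inserted rather than substituted, parameter
counts order `dmnet > mnet > unet3d` at equal `F`.

Weight initialisation is variance-scaling fan-in. **Weight transfer**
(pre-training on a male-pelvis task with five structures, then fine-tuning
on the four-channel task) copies every parameter tensor with matching name
and shape and freshly initialises the output head when class counts differ;
a manifest records copied vs reinitialised tensors.

The networks run on a compact numpy reverse-mode autodiff toolkit written
for this package (`pelviseg.nn`): im2col 3D convolution with stride and
dilation, transposed convolution, instance norm, dropout, softmax, Adam.
It targets CPU desk-scale grids (tens of thousands of voxels) with batch
size 1; it is not a general deep-learning framework.

## Data conventions and preprocessing

Volumes are channel-last `(X, Y, Z[, C])` in stored voxel order with
spacing in mm; no anatomical reorientation is attempted. On disk, images and
integer label index maps are NIfTI-1; one-hot expansion is in-memory.

* **Bias correction** is a pluggable hook delegating to SimpleITK's N4
  implementation; failures degrade to identity with a warning.
* **Resampling** to the network grid (clinical default 256x256x64 at
  1.64x1.64x3 mm) aligns physical centres, interpolates the image linearly
  and the label index map by nearest neighbour, and fills out-of-field
  regions with zero intensity / background. Centring the field of view is a
  design choice; only "cropped and resized" is fixed by the protocol.
* **CGU merging** takes the voxelwise union of the cervix, GTV and uterus
  channels (overlaps counted once).
* **Class labels**: bladder entry = 1 iff the largest inscribed-sphere
  radius (max of the anisotropic distance transform, volume border counted
  as background) strictly exceeds 17 mm; CGU entry = 1 iff GTV volume
  strictly exceeds 4x the uterus volume. "Maximum radius" is interpreted as
  the inscribed-sphere radius (robust to irregular shape) and "size" as
  physical volume; both interpretations are config-exposed choices, and both
  thresholds are strict.
* **Intensity normalisation** before training is a per-volume z-score; some
  normalisation is required for stable training and none is prescribed.
* **Post-processing** keeps, per foreground channel, only the largest
  26-connected component (ties to the first component in scan order);
  removed voxels become background. 26-connectivity is the standard choice
  for 3D blob retention and least prone to splitting thin structures.

## Evaluation metrics and statistics

DSC `2|A^B|/(|A|+|B|)` (1 when both masks are empty); Hausdorff distance and
mean surface distance between mask surfaces (voxels with a face-adjacent
background or border neighbour), on voxel centres with anisotropic spacing,
in mm. HD is the full maximum (an unqualified "Hausdorff distance" means the
100th percentile); MSD is the symmetric average of the two directed means.
Approaches are compared per structure and metric with the two-sided paired
Wilcoxon signed-rank test: zero differences dropped, exact null for n <= 25
without ties, tie-corrected normal approximation otherwise, significance at
0.05 uncorrected for multiplicity.

## Synthetic phantoms

The generator emulates the geometry and contrast of the clinical T2-weighted
data, not its physics: bright ellipsoidal bladder, intermediate CGU built
from 2-3 overlapping ellipsoids (uterus, small cervix, tumour of
controllable volume), dark curved-tube rectum (capsule around a quadratic
Bezier centerline, radius calibrated on the voxel grid so the rasterized
volume matches the request), laid out anterior-to-posterior with >= 2-voxel
margins, pairwise disjoint (fixed precedence bladder < CGU < rectum on
contested voxels), each a single 26-connected component. Intensities get a
smooth multiplicative polynomial bias field (order 2, amplitude 0.2) and
additive Gaussian noise (SD 0.05 on a [0.2, 0.9] intensity scale).

Default volumes are the clinical medians (bladder 200, GTV 111.7, rectum
57.95 cm^3); population sampling draws volumes log-uniformly either across
the full clinical ranges (bladder 30.08-721.8, GTV 11.42-712.31, rectum
19.3-213.45 cm^3; uterus 30-250 cm^3 as a plausible adult range, not
reported clinically) or in a narrow band around the medians. The default
phantom grid is 48x48x16 at 5x5x10 mm (240x240x160 mm field of view);
the full-range population uses 64x64x32 at 5 mm isotropic so the largest
organs fit. Draws whose geometry cannot be placed are redrawn

What passing phantom experiments does **not** show: robustness to real MR
appearance (coil profiles, partial volume, motion), to inter-observer
contour variability, or to anatomy outside the generator's shape family
(e.g. the extreme endometrium cases flagged as outliers clinically).

## Augmentation

Four operations — elastic deformation (Gaussian displacement field on a
~32 mm control grid, SD 4 mm), affine warp (scale 0.9-1.1, shear +-0.05),
single-axis rotation (+-15 deg), integer-voxel shift (+-10 in-plane, +-3
through-plane) — applied jointly to image (linear) and label map (nearest,
re-one-hotted). Each augmented copy applies a random non-empty subset; the
original is kept alongside the default 9 copies, so 42 series yield 420.
The magnitudes are anatomy-preserving defaults; only the operation set and
the factor 9 are fixed by the protocol.

## Training protocol

Adam, learning rate 0.001, batch size 1, fixed epoch budget (no validation
split, no early stopping). Patient-level k-fold cross-validation: patients
are shuffled by seed and dealt round-robin (assignment method is an open
choice); all series of a patient travel together; outlier-flagged series
stay in training sets but never in test lists. Pre-training for transfer
uses a 10-epoch budget by default.

## Desk-scale problem sizes

The package's experiments are sized for a single CPU: phantom grids of
48x48x16 voxels, base filters 8, 2-fold cross-validation, ~8-10 epochs.
The end-to-end acceptance experiment trains DM-Net+PDL and U-Net+Dice on 40
phantoms (8 patients x 5 series) and checks a mean held-out bladder DSC of
at least 0.75; the full clinical configuration (256x256x64, base filters 32,
5-fold, 50 epochs) is expressible in the same configs but is not exercised
by the tests.

## Numerical choices

* Softmax argmax ties harden to the lowest channel index.
* Losses: 0/0 cases are 0 (dice and bbox); DCE clips predictions at 1e-7.
* Crisp loss evaluation runs in float64 (oracle agreement to 1e-12);
  training runs in float32.
* Connected-component ties keep the component first reached in scan order.
* Wilcoxon: zero differences dropped; exact method only when |differences|
  are untied.
* Forward passes are bit-reproducible for a fixed seed on one platform;
  across BLAS builds agreement is ~1e-6.

## Known limitations

* No DICOM / RT-STRUCT ingestion; NIfTI only.
* The numpy NN toolkit is single-sample and CPU-bound; full clinical-scale
  training is out of its intended range.
* Phantom realism is geometric, not physical (no k-space, relaxometry or
  partial-volume model).
* The bounding-box loss treats footprints axis-aligned; for strongly curved
  structures (rectum) it is a loose constraint.
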