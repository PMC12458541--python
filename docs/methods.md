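# Methods

## The data model

Input is a transcript table — one row per detected transcript with FOV id,
cell id (0 = extracellular), gene name, global pixel coordinates, z-slice
and subcellular compartment — plus a cell table of center coordinates.  Both
are read from CSV or Parquet; Parquet reads are column-selective so a join
that only needs coordinates never materializes the rest.  The gene
vocabulary is an ordered list of names whose line order fixes the channel
order for every tensor downstream.

## Patch extraction

Every cell is the center of exactly one square patch of side `S` pixels
(default 600).  Membership is a box (Chebyshev) criterion with half-width
`S/2` and half-open intervals: transcript `(x, y)` belongs to the patch at
floored center `(cx, cy)` iff `cx − S/2 ≤ x < cx + S/2` and likewise in y.
This is the only reading of "distance to the patch center less than the
patch size" that yields exactly `S × S` patches centered on each cell;
half-open intervals prevent boundary double counting.  Local coordinates are
offsets from the patch's low corner; transcripts may appear in several
overlapping patches but at most once per patch.  Cells near the FOV edge
keep their patch centered on them, with the out-of-FOV area simply empty —
the alternative (discarding edge cells) would bias the patch set against
tissue borders.  Sub-pixel centers are floored; transcript coordinates are
floored to integer pixels on entry.  The join is held to a brute-force
double-loop oracle in property tests.

## Reduction and rasterization

The reduction parameter `r` (default 2) maps local pixel `(x, y)` to bin
`(x // r, y // r)`, shrinking pixel count by `r²` (4 at r=2; r=3 needs 2.25×
less than r=2).  Default aggregation is **count**, not binary: the loss
weights need per-gene totals, and reduction can merge several transcripts
into one bin; binary mode is available for the full-resolution
presence/absence convention.  `densify` conserves transcript counts exactly
(tensor sum = record count) and `sparsify` inverts it at r=1.

## Model

`ModelSpec` declares input channels, input side and an encoder channel
schedule; everything else is derived.  Encoder layers are 3×3 stride-2
convolutions with no padding, each followed by LeakyReLU (slope 0.01 — a
conventional default, exposed as a parameter); batch normalization sits
after the final encoder convolution, before its activation.  The decoder
mirrors the schedule with transposed convolutions; since a stride-2
downsampling loses one bit of size information, the output padding (0 or 1)
of each transposed convolution is *solved for* so the mirrored side is exact
— `(n−1)·2 + 3 (+1)` must hit the recorded encoder side.  Batch norm follows
every decoder layer except the last; the final decoder layer keeps its
LeakyReLU, so reconstructions are unbounded and the loss operates on raw
values.  Convolutions keep biases even when followed by batch norm; under
this convention the closed-form parameter count of the `zipaer2` preset is
exactly 60,743,102 (≈61M) and `zipaer3` is 63,103,678 (≈63M).  Shape and
parameter oracles are closed-form and tested for exact equality against the
instantiated networks.

Where the deeper preset's description is ambiguous (whether its middle
encoder stage retains a batch norm), we place batch norm only after the
final encoder convolution; the parameter total rounds to 63M under either
reading.

## Loss

With `s_i` the total expression of gene `i` over the **training split** and
`s⁺` the positive totals:

    weight_i = median(s⁺) / s_i   (s_i > 0), else 0
    MSE_i    = mean over batch and both spatial axes of squared error
    L        = 1e6 · mean over {i : s_i > 0} of weight_i · MSE_i

Averaging MSE over batch and space makes the loss independent of batch and
patch size.  Zero-total genes are excluded from both numerator and
denominator — the weight is undefined at `s_i = 0`, and exclusion keeps the
loss finite without distorting the other weights.  A gene at the median
total contributes with weight exactly 1, and scaling all per-gene MSEs by a
constant scales the loss by the same constant.  The 1e6 factor is cosmetic.
Totals are computed on the training split only, so the validation loss is
measured under the same weighting the optimizer saw.

## Optimization

Adam (betas 0.9/0.999, eps 1e-8) at initial learning rate 1e-3.  Gradient
accumulation: micro-batches of `n_devices × per_device_batch` samples; each
micro-batch loss is divided by `accumulation_steps` before backprop and the
optimizer steps once per group, so one update equals the mean-loss gradient
over the effective batch (`devices × batch × steps`; 9 × 2 × 4 = 72 in the
reference setup, giving ceil(190000/72) = 2639 steps per epoch at full
scale).  On a batch-norm-free model the accumulated update is numerically
identical to the full-batch update (tested at 1e-5 relative tolerance); with
batch norm the micro-batch statistics differ and exact equivalence is not
expected — a test documents the deviation.  `n_devices` is an arithmetic
multiplier emulating data parallelism in one process; actual multi-device
execution is out of scope.

The learning rate follows a reduce-on-plateau policy (factor 0.3, patience
8, relative threshold 0.01): an epoch improves only if its validation loss
is below the running-minimum loss by more than 1%; after 9 consecutive
non-improving epochs the rate is multiplied by 0.3 and the counter resets.
Tracking the running minimum (rather than updating "best" only on
significant improvement) guarantees that slow sub-threshold drift still
counts as a plateau.  Checkpoints (all parameters plus batch-norm running
statistics) are written at every validation improvement; restoring the last
checkpoint reproduces its logged validation loss exactly.

## The numpy NN engine

The package ships its own minimal CPU engine: Conv2d, ConvTranspose2d,
BatchNorm2d, LeakyReLU, Dropout (inverted, train-only), Flatten, Linear,
Adam, and the plateau scheduler, all with hand-derived backward passes.
Convolutions are evaluated offset-by-offset — one BLAS matmul per kernel
offset on a strided input slice — which bounds peak memory near one
input-sized temporary instead of a full im2col buffer; a zero batch passes
through the full 6078-channel preset in well under 2 GiB.  Every backward
pass is validated against central-difference numerical gradients in the
test suite.

## Synthetic data: what it emulates, and what it does not

The generator draws per-gene mean expression log-normally
(`gene_abundance_spread` = log-sd 1.5 gives the several-orders-of-magnitude
dynamic range that motivates the weighted loss), per-cell per-gene counts as
Poisson, and transcript positions as an isotropic Gaussian around the cell
center clipped to the FOV.  Defaults: 1 FOV of 2000 px, 50 cells, 100
genes, ~300 transcripts per cell, 10% uniform extracellular background
(cell_id 0), `cell_spread_px` 15 — about a quarter of the 64-px desk-scale
patch, mirroring the real geometry in which a patch contains its central
cell plus the fringes of neighbors.  A binary marker gene defines the
labels: marker-positive cells emit ≥1 marker transcript and have a block of
10 genes upregulated 3× (so the marker state measurably shifts the
transcriptome); negative cells emit none.  The log-normal/Poisson choice is
a stand-in for convenience, not an inference about any real dataset.

Not emulated: tissue morphology, nucleus/membrane geometry, z-stacks beyond
a constant slice, segmentation errors, cell-type structure beyond the
marker program, and spatial correlation between neighboring cells.  Passing
desk-scale tests therefore demonstrates that the machinery is correct and
that pretraining helps on a clean separable signal — not that any particular
accuracy transfers to real tissue.

## Classifier experiment

Patches are labeled by whether ≥1 marker transcript is *assigned to the
central cell* (cell-id match, not mere spatial presence in the patch); an
optional eligibility set stands in for the real experiment's cell-type
restriction (all simulated cells are eligible by default).  The labeling
operation therefore reads the cell-attributed transcript table rather than
the sparse patch store, which carries no cell ids.  Splits are stratified
70/30 (stratification stabilizes the small benchmark; the implementation
uses scikit-learn's splitter).  Both arms share one architecture — encoder
plus convolutional head — and hence parameter count; the pretrained arm
freezes the trained encoder (a config flag allows fine-tuning) and trains
only the head on latents with 2-class cross-entropy, while the baseline
trains everything from scratch.  Metrics are computed from confusion counts;
a zero-denominator metric is reported as NaN (undefined), never 0.

## Problem sizes and numerical choices

Desk-scale runs use the default synthetic config with 64-px patches at r=2
(100 × 32 × 32 tensors), a 2-layer model (schedule 32, 16; latent 16 × 7 ×
7), 30 training epochs, and 3 seeds for the classifier comparison — chosen
so the full pipeline trains in seconds to minutes on one CPU while leaving
every contract (shapes, conservation, equivalences) exactly testable.
Model parameters default to float64; the big presets are instantiated in
float32 where only shapes and counts are measured.  Degenerate inputs are
errors, not silent zeros: all-zero gene totals, empty splits, non-finite
losses, out-of-bounds records and impossible mirrors all raise typed
exceptions.

## Known limitations

Single-process CPU execution only; no GPU, no real multi-device data
parallelism, no mixed precision.  The full-scale presets are instantiable
and their arithmetic is verified, but training them to the published loss
levels requires the real dataset and cluster-scale hardware, which is out
of scope.  The classifier benchmark is small (50 patches) and its absolute
accuracies are noisy; only the paired comparison across seeds is
meaningful.
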