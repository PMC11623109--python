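# Methods

## The model

`ultraseg` implements an attention-gated multi-resolution U-Net for binary
lesion segmentation of grayscale B-mode breast ultrasound images. The
network is a five-level encoder–decoder:

- **Encoder.** Five multi-res blocks with filter widths 32, 64, 128, 256,
  512 (configurable), separated by 2×2 max-pooling. Input sides must be
  divisible by 16 so the four poolings are exact halvings; a 256×256 input
  reaches a 16×16×512 bottleneck.
- **Multi-res block.** Three serial 3×3 conv–BN–ReLU sub-blocks whose
  outputs (effective receptive fields 3, 5 and 7) are concatenated, with
  the output-filter budget split in equal thirds and the remainder assigned
  to the last sub-block, plus a residual branch `H(x)` — a 1×1 conv–BN
  projection, or the identity when channel counts agree. The block output
  is `y = F(x, {w_i}) + H(x)`, a plain sum with no post-activation
  (pre-activation residual style). Sub-blocks use conv → batch-norm → ReLU
  ordering, the stable convention for residual CNNs.
- **Attention gate.** For an encoder feature `x` and a like-shaped decoder
  feature `x_up`, a bias-free 1×1 convolution projects `x` to 32
  intermediate channels; the parameter-free channel mean of that projection
  through a sigmoid gives a per-pixel scalar `a ∈ (0,1)`, and the gate
  returns the convex combination `a⊙x + (1−a)⊙x_up`. Every output element
  therefore lies between the two inputs — this is property-tested. The
  bias-free projection with parameter-free reduction is the only reading
  consistent with the audited gate counts (`in_channels × 32` at every
  level).
- **Decoder.** Each stage upsamples bilinearly (parameter-free), halves
  the channel width with a multi-res block, and merges the encoder skip
  through the attention gate. The convex-combination merge **is** the skip
  connection: concatenation would double the channel width and break the
  audited per-stage dimensions, so none is used. A final full-resolution
  multi-res block (32→32) refines the merged features before a 1×1 output
  convolution; the sigmoid of its logit map is the per-pixel foreground
  probability. Probabilities are binarised at 0.5, ties mapping to
  foreground.

### The declarative graph and the two parameter readings

`assemble_model` builds a pure description of the architecture — 29 rows of
(block, name, filters, dimensions, params, operation) — that can be audited
without instantiating weights. Two parameter interpretations coexist:

- `table_audit` reads each multi-res row as a single 3×3 convolution with
  bias and each gate as the bias-free 1×1 projection. This is the
  arithmetic under which the published per-row counts of this architecture
  are reproducible: all ten gate rows and eight of the ten multi-res rows
  match exactly. Three rows do not follow from any consistent conv
  arithmetic (the first encoder row fits a 32→32 conv + BN rather than a
  1-channel input; the bottleneck row appears to have lost a leading
  digit; the output row fits a 64→1 conv although its input is 32-channel)
  and are excluded from the audit but kept in the reference table for
  diffing. The decoder rows' implied in/out channel pairs (256→256,
  256→128, 256→64, 256→32, 128→32) are stored as row data because no
  single channel-flow rule generates them.
- `canonical` counts the full executable block (serial thirds, batch-norm
  parameters, residual 1×1 conv). Canonical counts are generally *smaller*
  than the single-conv reading because the serial thirds factorise the
  channel map; e.g. 64→128 is 65,660 canonical vs 73,856 under the audit
  reading.

### Eq.-style hard masking

The hard binary masking utility (`mask_features`: keep features on the mask
support, zero elsewhere) is provided as a standalone operation and is *not*
inserted into the forward pass; inside the network, attention is the soft
gate described above. The hard mask is idempotent and zeroes exactly the
off-support elements, both property-tested.

## The NumPy engine

The network runs on a small, self-contained NumPy engine
(`ultraseg.nn`): 1×1/3×3 same-padding convolution, batch normalisation
(momentum 0.1, eps 1e-5, running statistics for inference), ReLU, 2×2
max-pooling, matrix-based 2× bilinear upsampling with an exact transpose
backward, the attention gate, and Adam (β₁ 0.9, β₂ 0.999, ε 1e-7). Every
layer implements an explicit backward pass; all gradients are verified
against central differences in float64 in the unit tests. Tensors are
float32 NCHW. Weight initialisation is He-normal, seeded from
`ModelConfig.seed`; the output bias starts at −2 (sigmoid ≈ 0.12), a
background-prior initialisation reflecting that lesions cover a small
fraction of a scan — it removes the early epochs an imbalanced head would
otherwise spend drifting toward the background rate. Transpose-convolution
upsampling is accepted by the config for audit purposes but not executable;
bilinear is the default and the audited variant.

## Training

Binary cross-entropy over pixels (probabilities clamped to
[1e-7, 1−1e-7]), Adam with learning rate 1e-3, batch size 8, a 100-epoch
default budget, and a reduce-on-plateau schedule: if validation loss fails
to improve by more than 1e-4 for 5 consecutive epochs the learning rate is
halved, floored at 1e-5. The plateau settings are framework-conventional
defaults for the named callback. The 85/15 train/eval split takes
`floor(0.85·n)` training samples (697 → 592 train / 105 eval). k-fold
cross-validation uses near-equal folds (sizes differ by ≤ 1), stratified by
class when labels are present; within each fold's training portion a 10%
slice drives the plateau callback only. Per-fold confusion counts are
pooled over all pixels, the metric suite is derived per fold, and folds are
averaged unweighted (mean ± sample std). Augmentation — flips (p = 0.5
each), rotation ±25°, scaling 0.9–1.1, 90% crop resized back — is applied
on the fly with a shared transform for image and mask (bilinear vs
nearest-neighbour interpolation); magnitudes are deliberately mild and
label-preserving. No early stopping; the epoch budget is fixed.

## Metrics

ACC, SEN, SPE, PRE and F1 from pooled pixel confusion counts; Dice
2|A∩B|/(|A|+|B|), which equals F1 on binary masks (asserted to 1e-12 on
random pairs); ROC-AUC by the Mann–Whitney pairwise-ranking statistic with
ties counting ½ — exact for finite samples, no threshold grid. Degenerate
denominators: no actual positives → SEN = 1; no predicted positives →
PRE = 1 if nothing was missed else 0; two empty masks → Dice = 1. AUC
requires both classes and raises otherwise.

## The phantom generator

The generator emulates the features of clinical B-mode breast images that
the pipeline needs to see: a smooth background field with a mild axial
depth gain, multiplicative gamma-distributed speckle (mean 1, shape 4,
lightly blurred to mimic point-spread correlation), hypoechoic lesions
(interior intensity reduced by the contrast fraction, default 0.5 benign /
0.6 malignant), punctate bright calcifications (discs ≤ 3 px), and
posterior acoustic shadowing below lesions (probability 0.3 benign / 0.5
malignant). Lesions are star-convex: ellipses with a low-order sinusoidal
radial perturbation whose amplitude sets boundary irregularity — 0.06 for
benign, 0.22 for malignant, so malignant boundaries are strictly more
tortuous on average (verified over 20 seeds via the isoperimetric ratio
P²/4πA). Normal-class images contain no lesion and get an all-zero mask
file so the reader contract is uniform. Default frame is 256×256, the
best-performing training resolution for this architecture. Everything is a
pure function of (parameters, seed); PNG trees are byte-identical across
reruns.

What the phantom does **not** model: physically based acoustic wave
propagation, refraction and reverberation artifacts, heterogeneous
anatomy (ducts, fascia, ribs), probe-dependent texture, or annotation
noise. Passing tests on phantoms therefore demonstrate that the
architecture, optimisation and evaluation machinery are correct and can
learn hypoechoic-blob segmentation — they say nothing quantitative about
clinical-image performance.

## The desk-scale learning surrogate

Full-scale training (256×256, 100 epochs, hundreds of clinical images) is
far beyond a single-CPU test budget. The stand-in task fixes: reduced
filter schedule 8–128, 64×64 frames, lesion contrast 0.7, 64 training / 4
validation / 8 held-out phantoms, at most 30 epochs, three seeds. Under
these conditions the held-out Dice averages ≈ 0.93 (≥ 0.9 required), the
training loss decreases, and the learning-rate trace is non-increasing.
These sizes were chosen once as a realistic desk-scale task; the benchmark
module (`ultraseg.benchmark`) freezes them so test and acceptance runs are
comparable.

## Numerical choices and degenerate inputs

- Probability clamp 1e-7 before logs (loss and `segment` output) so
  saturated logits never produce infinities or exact 0/1.
- Binarisation threshold 0.5 with ties to foreground.
- Bilinear upsampling uses half-pixel centre alignment
  (`align_corners=False` convention); max-pooling requires even dims,
  guaranteed by the divisible-by-16 input contract.
- Multi-res blocks need ≥ 3 output channels (one per serial sub-block).
- Image sizes not divisible by 16 in the resolution harness are padded
  reflectively up to the next multiple (500 → 512) and predictions cropped
  back before scoring.
- Multiple masks per image combine by union; 8-bit masks threshold at
  > 127; RGB inputs collapse to luminance.
- BCE gradient is taken with respect to logits, `(p − y)/N`, fusing the
  sigmoid for stability.

## Known limitations

- The engine is CPU-only NumPy; it is meant for desk-scale experiments and
  audits, not for full-resolution clinical training runs.
- Batch-norm running statistics update during any train-mode forward pass,
  so a zero-learning-rate run freezes weights but not inference-mode
  statistics.
- The canonical multi-res filter allocation (equal thirds) and the gate's
  channel-mean reduction are the package's own resolutions of
  underdetermined design points; both are recorded above and in the audit
  so alternatives can be compared.
- `cross_validate` retrains one network per fold from scratch; at clinical
  sizes this is the dominant cost and is not parallelised.
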