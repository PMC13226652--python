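# Methods

`magcardia` implements a complete representation-learning pipeline for
64-channel magnetocardiography (MCG): a physics-based signal simulator, the
preprocessing and quality-control chain, SimCLR-style contrastive
pretraining of a temporal-convolutional encoder, task probing with
patient-stratified cross-validation, and Grad-CAM attribution. Because no
clinical MCG cohort is publicly available, every quantitative claim the
package makes is established on simulated data whose generative structure
is fully known; this note records the model, the defaults, and what the
synthetic experiments do and do not show.

## Forward model and simulator

The heart is a point current dipole at `(0, 0, -0.06)` m below the sensor
plane. Each sensor at position `r` records the normal component of the
free-space dipole field,

    Bz(r) = (mu0 / 4 pi) * (m x (r - r0))_z / |r - r0|^3,

which depends only on the in-plane moment components. Volume currents are
omitted: over a horizontally layered conductor the normal field component
is dominated by primary (intracellular) currents, and the pipeline never
uses absolute amplitude (see normalisation below). Field values are in
arbitrary consistent units.

The sensor array is four concentric rings of 16 sensors at radii
3.5 / 7 / 10.5 / 14 cm, standoff 1 cm (configurable). The exact clinical
grid is not reproduced; any circular layout with comparable thorax
coverage serves the same role.

The dipole moment traces a P-QRS-T cycle built from Gaussian bumps in beat
phase (the standard dynamical-ECG construction) with amplitudes
1.2 / -5 / 30 / -7.5 / 0.75 (P/Q/R/S/T), widths 0.25 / 0.1 / 0.1 / 0.1 /
0.4 rad, and a fixed in-plane direction per wave so the field map rotates
over the cycle. RR intervals are Gaussian (mean 0.85 s, sd 0.04 s,
truncated at +-3 sd, keeping beats ordered).

Class-conditional effects (each scaled by a non-negative `effect_size`;
zero reproduces the control class bit-exactly because the class effect
draws from a separate random stream):

* **cad_lad / cad_lcx / cad_rca** — regional repolarization abnormality
  with two components. A secondary dipole displaced 5 cm toward the
  anterior-septal (+y), lateral (+x), or inferior (-y) territory, active
  in a Gaussian window centred in the ST-T interval (phase 1.1 rad, width
  0.35 rad; about 150 ms after the R peak at the default heart rate),
  amplitude `3.5 * effect_size` moment units — the territory-specific
  spatial signature. And a global T-wave change: the T axis rotates
  toward the territory direction by `0.3 * effect_size` of the angular
  gap, with amplitude x(1 + 0.3 es) and width x(1 + 0.2 es). The second
  component matters because it expresses the disease along the same
  morphology axes that vary between patients, which is the premise under
  which representations learned by instance discrimination transfer to a
  disease probe.
* **low_ef** — R amplitude scaled by `1 - 0.35 * effect_size`, QRS widths
  by `1 + 0.5 * effect_size`.
* **af_substrate** — P-wave width `x (1 + 0.8 * effect_size)`, a second
  delayed P bump, and per-beat jitter of P amplitude and timing.

Patients differ anatomically: per-patient factors jitter each wave's
amplitude (sd 20%), width (sd 10%) and in-plane direction (sd 10
degrees), and displace the heart position (sd 1 cm in the sensor plane),
all scaled by `morph_variability` (default 1, 0 disables). Without this
no two-patient distinction exists beyond noise, contrastive pretraining
degenerates to encoding segment-specific artefacts, and nothing learned
self-supervised can transfer.

Noise, relative to the clean recording's peak amplitude: white Gaussian
(sigma 0.05), per-channel sinusoidal baseline drift at 0.05-0.3 Hz
(amplitude 0.5), 50 Hz line interference (amplitude 0.2), and channels
dropped with probability 0.03 and retained as zero traces. Default
recording length is 3 minutes per patient.

What the simulator does **not** emulate: torso conduction, sensor
calibration error, motion/respiration artefacts, ectopy or rhythm change,
inter-patient anatomical variability beyond RR statistics, and label
noise (an optional label-permutation utility exists instead). Passing the
synthetic experiments therefore demonstrates that the pipeline recovers a
spatio-temporally localised field perturbation under realistic
acquisition-style noise — not clinical performance.

## Preprocessing and quality control

Recordings are cut into non-overlapping 10 s windows (64 x 5000 at
500 Hz; trailing remainder discarded), then each window is filtered:
fifth-order Butterworth high-pass at 0.5 Hz followed by a second-order IIR
notch at 50 Hz (Q = 30), both applied forward-backward (zero phase) with
reflect padding. Segmenting before filtering keeps windows independent;
the ~1 s high-pass edge transient is accepted and excluded where tests
measure interior behaviour.

R peaks are detected on the RMS trace across valid channels (robust to
per-channel polarity of magnetic maps), band-passed 5-30 Hz, with an
adaptive threshold of 0.5x the rolling 2 s maximum and a 200 ms refractory
period. On simulated data detections match ground truth to the sample.

The SNR metric stacks, per channel, windows from 150 ms before to 450 ms
after each complete R peak (300 samples), reconstructs the beat matrix
from its top-k singular triplets (k = 3 by default), and defines

    SNR_dB = 10 log10( P_reconstruction / P_residual ),

capped at +80 dB, averaged over valid channels with at least two complete
beats. Segments with mean SNR < 5 dB are excluded (equality passes). The
decibel unit, k, the beat window, and channel-mean aggregation are
implementation choices exposed in configuration.

## Encoder and contrastive pretraining

The encoder treats the 64 channels as input feature maps and convolves
only over time: four residual blocks (conv-ReLU-conv with a 1x1 strided
shortcut), global average pooling over time, and a linear map to the
embedding. Default architecture: widths 32/64/128/128, kernel 15, stride 2
per block, 128-d embedding. A desk-scale variant (widths 8/16/32/32,
kernels 8/9/9/9, strides 8/2/2/2, 32-d embedding) is first-class and used
by all synthetic experiments; its first block is a non-overlapping patch
convolution, which keeps single-CPU training practical at 5000-sample
inputs.

Each segment is scaled to unit RMS before the first convolution. Absolute
field amplitude varies with standoff and acquisition conditions and is not
a morphology feature; without this normalisation the simulated ~1e-3-unit
fields produce vanishing gradients.

Pretraining follows SimCLR: two independent views per segment
(per-channel Gaussian noise at 1.0x the channel sd, dropout of 10% of
valid channels replaced by moment-matched Gaussian noise, and per-channel
contiguous masking of up to 75% of the segment with the channel mean,
applied in that order), a 2-layer projection head, and the NT-Xent loss at
temperature 0.1 over in-batch negatives. Optimisation: AdamW, lr 1e-3,
weight decay 1e-4, batch 32, cosine decay to 1% of the initial rate over
the schedule (100 epochs by default; 10 in the desk benchmark). All
randomness (weight init, data order, augmentation) derives from one seed
via independent streams, so loss traces are bit-reproducible.

The whole network stack (1-D convolution via im2col + GEMM with explicit
backward passes, Adam/AdamW, NT-Xent gradient) is implemented in NumPy in
`magcardia.nn` / `magcardia.encoder_ssl`. Correctness is guarded by
finite-difference gradient checks, a brute-force NT-Xent oracle, and a
hand-derived Grad-CAM oracle in the test suite.

## Probing, fine-tuning, and evaluation

Each task head rescales its input embedding to `sqrt(D) * e / ||e||`,
then applies dropout(0.2), a 64-unit dense layer with swish, and a
sigmoid output. The rescaling matters more than it looks: a
contrastively trained encoder emits embeddings at an arbitrary (often
large) scale because the cosine objective only constrains directions, and
an unnormalised head is so badly conditioned that fine-tuning from the
pretrained state can lose to training from scratch purely as an
optimisation artefact. Per cross-validation fold: 5 warm-up epochs with the
encoder frozen (embeddings computed once; the encoder checksum is asserted
unchanged), then joint optimisation of encoder and head (30 epochs by
default; 15 in the desk benchmark), minimising class-frequency-weighted
binary cross-entropy (`sum(w l) / sum(w)`) with Adam. Fine-tuning defaults
are lr 1e-3 (head and joint) and batch 16: at desk scale (~100 training
segments for ~20 epochs) smaller learning rates leave too few effective
optimisation steps to converge, and the learning rate is not a quantity
the protocol pins down. Both are configurable.

Folds are assigned to patients, stratified by label, so no patient's
segments span train and validation; an audit utility rejects leaky
assignments. Segment scores are averaged per patient (mean; median
available), and patient-level AUC (rank statistic, ties half credit),
sensitivity, specificity, accuracy, precision and F1 are computed at a
fixed 0.5 threshold (no validation-set threshold tuning). Summaries are
fold means with 95% t-intervals; patient-bootstrap intervals are available
for ROC bands. The supervised baseline trains the identical architecture
end-to-end from random init for the same total epochs, with no warm-up
freeze.

## Attribution

Grad-CAM targets the last convolutional block: the probe logit's gradient
is averaged over time per feature map, the rectified weighted sum of maps
is linearly upsampled to 5000 samples, aligned to R peaks, and averaged
into a beat profile (max-normalised). Grad-CAM collapses the input
channels, so per-channel scores use time-aggregated |gradient x input| at
the input tensor — a documented substitute, not a uniquely determined
rule — projected onto sensor coordinates; missing channels score exactly
zero. The aggregation can optionally be restricted to a phase of
interest (a boolean time mask, e.g. the ST-T interval around each
detected beat), which the benchmark uses for its territory-sector check.

## Synthetic benchmark (acceptance experiments)

60 patients (30 control / 30 `cad_lcx` with effect size 1.0), 0.5 min of
recording each (three 10 s segments per patient — a problem size chosen
for single-CPU runs; the simulator default remains 3 min), default noise.
Pipeline: preprocess, QC, pretrain 10 epochs on all segments, 5-fold
patient-stratified probing (5 warm-up + 15 joint epochs). Checks: mean
patient AUC above 0.8; a label-permuted rerun near chance (0.35-0.65); a
few-label comparison (20 labelled patients, 2-fold CV, 3 seeds) requiring
pretrained probing to match or beat the supervised baseline on average;
and Grad-CAM localisation (beat-profile importance higher inside the
ST-T window, 40-350 ms post-R, than outside; the centroid of ST-T-window
channel importance in the lateral half-array in at least 4 of 5 folds).
`scripts/acceptance.py` reruns all of this from scratch and writes the
numbers as JSON.

## Numerical choices and limitations

* float32 throughout the network; SVD, filters, losses and metrics in
  float64.
* SNR cap at +80 dB guards residual underflow on exactly low-rank input.
* Channel-dropout count rounds half to even with a floor of one channel
  when the fraction is positive; mask lengths are uniform on
  {0..floor(0.75 T)} (maximum-entropy reading of "up to ~75%").
* Degenerate inputs: flat segments and single-class folds raise typed
  errors; all-zero channels pass through filters, are excluded from SNR
  means, are never augmented, and attribute exactly zero importance.
* The NumPy training stack is desk-scale: no GPU, no mixed precision, no
  data parallelism; the full-scale encoder config trains correctly but
  slowly, and the desk variant is the supported experimental scale.
* Grad-CAM beat profiles sit on a high baseline everywhere in the beat —
  QRS activations dominate feature magnitude at every layer — so the
  in-window versus out-of-window margin of the temporal localisation
  check is modest and varies with the simulated cohort; the spatial
  (sector-centroid) check is markedly more stable.
* Contrastive pretraining at 60 optimiser steps (benchmark scale) learns
  view-invariant structure but linear separability of the class effect in
  the frozen embedding is not guaranteed; the probing protocol's joint
  phase supplies the task-specific adaptation, as in the original
  fine-tuning design.
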