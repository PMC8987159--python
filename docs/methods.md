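# Methods notes

This note records the modeling choices behind `audenc`, what the
synthetic data do and do not emulate, and the numerical conventions that
matter when interpreting its outputs.

## Stimulus timing

All timing derives from a `StimulusSpec`: audio sampling rate, TR, and
corpus layout. The excerpt duration must be an integer number of TRs and
the TR an integer number of audio samples; at the full protocol
(16 kHz, TR 1.5 s, 90-s excerpts) one excerpt yields exactly 60 windows
of 24,000 samples, a 21-excerpt corpus yields 1,260 windows, and 21
excerpts × 6 subjects yield 126 encoding samples. Windows are
consecutive and non-overlapping; a trailing remainder shorter than one
window is discarded. Excerpts are treated as independent, gapless
streams — presentation order effects and inter-excerpt gaps are not
modeled.

## The auto-encoder

- **Convolutions** are stride-1 with same padding, so conv layers
  preserve temporal length and all reduction happens in max-pooling.
  The first pooling stage has factor 1 (no reduction) and the remaining
  three halve the length; this is the only factor assignment that
  reproduces the pooled lengths 24k/12k/6k/3k for a 24k input, given
  length-preserving convolutions.
- **Switch un-pooling**: pooling records each region's argmax (leftmost
  maximum on ties, deterministically); un-pooling places the pooled value
  back at that offset and zeros elsewhere. Inputs not divisible by the
  total pooling factor are right-truncated up front (never padded);
  impossible at the default configuration.
- **Decoder mirror**: the decoder's j-th deconvolution uses the kernel
  length of the (L+1−j)-th encoder layer and maps its channel count back
  toward the input, ending in a single channel. Activations: linear for
  the first encoder conv and the last decoder deconv, ReLU elsewhere.
- **Objective**: mean squared reconstruction error plus κ·ΣW² over conv
  weights (κ = 0.001). Biases are excluded from the penalty. The
  optimizer's weight decay (0.001) is implemented as *decoupled* decay
  (AdamW-style), a separate mechanism from the κ term, because the two
  are configured independently.
- **Optimization**: Adam with β₁ = 0.5, β₂ = 0.999, ε = 1e−8, batch 32,
  learning rate 2e−4 at full scale. Weights are seeded Glorot-uniform.
  Training stops when the best epoch loss fails to improve by a relative
  1e−5 for 50 consecutive epochs, or at `max_epochs`.
- **Implementation**: pure numpy (im2col + matmul forward, matmul +
  k-tap scatter backward), verified against central-difference gradients
  to ~1e−7 relative error in the test suite. Inference passes can run in
  float32 (`compute_dtype`), which matters only for the large full-scale
  feature extractions; training is float64.

## Feature pipeline

Each pooling layer's (tᵢ × cᵢ) map is averaged over time to a
cᵢ-vector per window; an excerpt's windows stack in stimulus order to an
(n_windows × cᵢ) design. Features are computed per window independently
(no cross-window context), matching the per-TR sample definition.

The HRF is the canonical double-gamma: response gamma with delay 6 s,
undershoot gamma with delay 16 s, both dispersions 1 s, undershoot ratio
1/6, duration 32 s, sampled at multiples of the TR (22 taps at 1.5 s) and
peak-normalized to 1. Peak normalization is inert downstream: the
regression coefficients absorb the scale and PCC is scale-invariant.
Convolution is causal with zero initial conditions, truncated to the
excerpt's row count — hemodynamics cannot precede the stimulus, and no
wrap-around is allowed. A cross-check against the SPM-convention
double-gamma in nilearn is part of the test suite.

## Encoding model

The per-voxel objective uses the 1/(2m) residual scaling, so the
published λ grid {0.05, 0.10, 0.15} is meaningful as-is; the solver
(scikit-learn coordinate descent, tolerance 1e−8, no intercept) natively
implements exactly this convention, and the tests pin it against the
closed-form soft-threshold solution on orthonormal designs and against
ordinary least squares at λ = 0.

Conventions worth knowing:

- Voxel series are normalized to zero mean and unit (population) SD per
  sample; constant series are flagged missing and excluded from all
  averages.
- Design columns are z-scored within each sample before fitting (constant
  columns dropped and recorded). The motivation is comparability of λ
  across layers whose channel scales differ; the voxel side of the
  normalization is part of the protocol, the feature side is this
  package's choice.
- A voxel whose fitted coefficients are all zero predicts a constant;
  its PCC is reported as 0 (no predictive power) rather than undefined.
  NaN is reserved for invalid (constant-series) voxels.
- λ selection holds out one (excerpt, subject) sample per fold, fits on
  the remaining samples' stacked designs, and scores the held-out sample
  by mean PCC over voxels; fold scores average unweighted, and ties break
  toward the larger (sparser) penalty. Averaging over voxels before
  folds is a choice; the alternative order is not implemented.

## Group inference

Per-sample performance maps are z-scored across voxels ("independently
normalized" is read as within-map, across-voxel normalization, making
maps comparable before aggregation). The group test is a one-sided
one-sample t-test per voxel (alternative: mean > 0), df = n−1; t converts
to Z by probability matching (Z = Φ⁻¹ of the t CDF), the standard
neuroimaging convention. Because p < 0.01 and Z ≥ 2.3 are not exactly
equivalent at finite df, both criteria are applied conjunctively. No
multiple-comparison correction is applied; surviving-voxel counts are
reported to keep that explicit. Zero-variance voxels take an explicit
infinite-t path with Z capped at 37 (the ceiling of numerically
representable tail quantiles) and a `capped` flag. Paired comparisons
run the same machinery on per-voxel map differences with matched sample
identifiers.

## Supervised baseline

The classifier reuses the encoder block structure, adds global average
pooling over the deepest pooled map and a softmax head, and trains with
cross-entropy/Adam/batch 32. Early stopping holds out 10% of training
windows and restores the best epoch's weights at patience 10 (both
configurable; the strategy is named in the protocol, its parameters are
this package's defaults). The encoder can start from scratch (default)
or warm-start from a trained auto-encoder. Layer probes use an RBF-SVM
with C = 1 and the median-heuristic bandwidth inside a per-fold
standardization pipeline, under seeded stratified 5-fold CV; supervised
"hierarchical features" are the classifier-encoder's pooling outputs,
run through the identical feature pipeline.

## Synthetic data: what it emulates, what it does not

The audio generator produces three spectrally disjoint families —
harmonic note stacks in a low band, amplitude-modulated high-band noise,
and syllable-gated formant-like chirps — standing in for classical
music, pop music and speech. They preserve the property the analysis
needs (categories distinguishable from spectra; features that differ
across layers) but none of the statistical richness of real music or
speech. Simulated BOLD inverts the encoding model generatively: a
responsive voxel is `D_layer · w + ε` with exactly k = 5 nonzero weights
of magnitude Uniform[0.5, 1.5] and random sign, ε i.i.d. Gaussian with
SD set to (signal SD)/SNR (SNR 5 by default); null voxels are pure noise.
There is no scanner drift, motion, physiological noise, spatial
autocorrelation, or hemodynamic variability across voxels — so passing
tests demonstrate the correctness and calibration of the *procedure*,
not performance on real recordings.

All randomness flows from explicit seeds: corpus excerpts use per-(category,
excerpt) child generators of one seed; the pipeline derives one seed per
stage from the run seed via named seed sequences. Reruns with the same
config are bit-identical (the manifest records SHA-256 checksums per
artifact).

## Problem sizes

Two scales are used. The full published scale (16 kHz, 24k windows,
32–256 channels) is exercised for architecture construction and forward
passes — the dimension checks — but not trained, since meaningful
training at that scale requires the original ~36k-sample pre-training
corpora. The desk scale (2 kHz audio, 30-s excerpts, 2 excerpts per
category, 2 subjects, filters 8/8/16/16, 60 epochs at learning rate
1e−3) trains end to end in about 90 s and is the standing condition for
the statistical tests: reconstruction quality, null calibration of the
threshold (2,000 voxels × 126 null maps), noiseless-voxel recovery
(PCC > 0.999 at λ = 0.001), and layer-selectivity enrichment (odds
ratio of responsive vs null voxels in each layer's suprathreshold mask,
pooled over seeded simulations). At this scale the demo's reconstruction
PCC (~0.67) reflects the short training schedule, not a property of the
architecture; the toy configurations in the test suite train to
held-out reconstruction PCC > 0.9.

## Known limitations

- The numpy implementation is single-threaded apart from BLAS matmuls;
  full-scale *training* is out of reach by design.
- Leave-one-out λ selection refits every voxel per fold and candidate;
  at scale one would cache coordinate-descent warm starts.
- The voxel grid used for NIfTI export is a synthetic compact box with
  identity affine — no anatomical meaning, no atlas labeling.
- The group model assumes exchangeable samples; subject identity is
  carried in the metadata but no random-effects structure is modeled.
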