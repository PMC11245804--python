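# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated on — including what passing tests do and do
not establish about real archives.

## Problem setting and model

The package labels records of a radiology archive without supervision. A
record is the triple (pixel array, DICOM tag mapping, exam-level narrative
diagnosis); an exam groups 1–15 records that share one diagnosis. Every
stage that estimates parameters — tag filtering thresholds, imputation,
encoders, autoencoders, the text corpus, PCA, distance normalisation and
cluster centres — is fitted on the training subset of an exam-level
80/10/10 split and then applied to all records, so no validation or test
information leaks into the fitted transforms. (The MissForest imputation is
the one transductive exception: it completes the table it is given, as the
algorithm has no transform step; the columns it operates on are chosen from
training fill rates only.)

### DICOM tags

1. *BPE reconstruction.* BodyPartExamined is blank in a large fraction of
   real headers. An ordered rule table `(regex, source tag, value)` fills
   blank cells from other tags; the first matching rule wins and non-blank
   cells are never overwritten. The rules ship as editable configuration;
   the defaults match the vocabulary of the synthetic generator.
2. *Array splitting.* Multi-valued tags (WindowCenter, PixelSpacing…)
   become suffixed scalar columns; ragged rows are padded with missing and
   logged.
3. *Filtering.* A column is kept when its training fill rate is ≥ 0.35
   (exactly 35 % is kept; only strictly sparser columns are dropped), it has
   ≥ 2 distinct values, it is not on the free-text name list, and it does
   not look like an identifier. The identifier heuristic — all non-missing
   values distinct — is applied to categorical columns only: continuous
   measurements are near-unique by nature and would otherwise be lost, while
   real identifiers (UIDs) are strings. A configurable drop-list supplements
   the heuristic.
4. *Imputation.* MissForest: initialise with column mean/mode, visit
   columns in ascending missingness, fit a random forest (scikit-learn,
   100 trees by default) on observed rows, predict missing rows, and stop
   when the change measure — normalised sum of squared changes over
   continuous cells plus mismatch fraction over categorical cells — rises
   (returning the previous iterate) or after `max_iter` sweeps.
5. *Encoding.* One-hot for categoricals (unseen categories at transform
   time give a zero block and a log entry); min–max scaling to [0, 1] for
   continuous columns with training-subset ranges, clipped at transform
   time.

The tag extractor is a dense autoencoder: three ReLU encoder layers
(512 → 200 → 125 by default), a linear bottleneck (32), a symmetric decoder,
MSE objective, Adam, mini-batch 32, at most 100 epochs, early stopping after
5 epochs without improvement with best-checkpoint restore. PCA (LAPACK /
ARPACK / randomised solvers) is the alternative extractor.

### Images

Export: `raw·slope + intercept`, then the linear VOI closed form

    y = clip(((x − (c − 0.5)) / (w − 1) + 0.5) · 255, 0, 255)

rounded half-up — the standard linear variant; the exact-linear and sigmoid
VOI variants are not implemented, which is documented behaviour. Records
missing any of the four rescale/window tags are excluded at assembly.
Multi-valued window tags use the first value pair (the conventional default
window). MONOCHROME1 data is intensity-inverted before windowing so polarity
does not split clusters. Single-valued images (value policy) and non-2-D
arrays (shape policy) are rejected before resizing. The resize scales the
longest side to 128 with bilinear interpolation and centres the content with
zero padding; odd remainders put the extra row/column at the bottom/right.

The image extractor is a mirrored convolutional autoencoder: per stage a
3×3 convolution + ReLU + 2×2 max pool with 64/128/256/512 filters, then a
final 3×3 convolution with 1,024 filters; the decoder mirrors with
nearest-neighbour upsampling and a linear output convolution. MSE, Adam
(learning rate 1e-6 by default), batch 32, at most 40 epochs; validation
loss is evaluated twice per epoch and training stops after 5 checks without
improvement. The embedding is the flattened final encoder feature map
(65,536 values for 128×128 input), optionally reduced by PCA (500
components, randomised solver, by default).

### Diagnoses

Tokenisation lowercases, removes the punctuation class
`,;:.()[]/\-!?"'«»*+=<>|{}~\`` and splits on whitespace; digits are kept.
Lowercasing is a package decision and is documented here because inflected
clinical text mixes case freely. The stemmer is injected as a pure
`word → stem` function; an identity stemmer and a minimal suffix stripper
(longest-match inflection suffixes, stems kept ≥ 3 characters) ship as
references, and a full morphological stemmer can be plugged in without
vendoring it.

The corpus holds every stem whose *training occurrence count* reaches
`min_word_frequency`, in lexicographic order. BOW returns raw counts over
that order; TF-IDF multiplies raw term frequency by the smoothed idf
`ln((1 + N)/(1 + df)) + 1` (natural log, N = training document count) — the
variant is fixed and documented since several conventions exist. The
paragraph-vector models train a shallow network with negative sampling
(5 negatives, noise distribution ∝ count^0.75, linearly decaying learning
rate): PV-DM predicts the centre word from the averaged document vector and
window context vectors; PV-DBOW predicts the document's words from the
document vector alone. Training and inference are single-worker with a
fixed document order and one seeded generator, so vectors are reproducible
to floating-point equality; inference freezes the word matrices and
fine-tunes only the new document vector.

### Fusion

Three representations, always in source order (diagnosis, tags, image):
plain concatenation; per-source distances to that source's cluster centres,
min–max normalised with scalar constants fitted on training distances and
clipped to [0, 1] (*clusterdists*); and the softmax of negated distances
per source (*clusterprobs*). The softmax consumes the *normalised*
distances by default — raw distances of high-dimensional sources saturate
the exponential and let one source dominate — with raw distances available
behind a flag. The per-source clustering configuration used to build the
cluster-space representations defaults to k-means/Euclidean κ=20 for
diagnoses, k-medoids/cosine κ=25 for tags and k-means/Euclidean κ=40 for
images.

### Clustering and selection

k-means is scikit-learn's (k-means++, `n_init=10` — a variance-reduction
choice covered by the repeated-run stability report). k-medoids is the
alternating (Voronoi) heuristic over a precomputed distance matrix with
k-means++-style seeding; PAM is not implemented and the choice is a
documented knob. Cosine distance is `1 − cosine similarity`. Ties in
nearest-centre assignment break toward the lowest index. An empty cluster
triggers one re-seed and is then flagged. Inertia is the sum of squared
distances to the closest centre under the model's own metric.

Elbow detection normalises the inertia curve to the unit square, flips it,
and takes the grid point with maximum difference to the diagonal (the
Kneedle construction; no spline smoothing, as the κ grids are short). A
flat difference curve — exactly linear decrease — has no knee; the κ with
maximum discrete second difference is returned and flagged.

Model selection ranks image and text extractors by `S` at the elbow κ and
tag extractors by the lowest `D_score` at their elbow, computed with the
already-selected image and text embeddings. `S` and `D_score` are defined
as 0 when any component is 0 (the harmonic-mean limit). In the
dissimilarity statistic, all `k(k−1)/2` pairs are enumerated up to a
seeded-sampling cap (10,000 pairs per cluster by default; exact mode
available); singleton clusters are excluded from the average rather than
contributing 0, and are reported.

### Post-filters

Clusters with fewer than `min_size = 100` members are removed. The entropy
cut-off operates on *normalised* entropy — the within-cluster entropy of
the modality or body-part labels divided by the log of that label set's
global size — so that a uniform mixture over 10 body parts scores 1.0 and
is removed at the 0.9 cut-off regardless of logarithm base; either label
type exceeding the cut-off removes the cluster. The oversampling plan
reports per-cluster replication counts up to the largest kept cluster;
the augmentation itself is a hook for downstream training code.

## Evaluation metrics

Entropies use natural logarithms; NMI and HS are ratios and therefore
base-invariant, which the tests verify together with agreement to an
independent reference implementation at 1e-10 on random contingency tables.
`NMI` is clipped into [0, 1] against floating-point noise. `HS` requires
non-constant ground truth; NMI of a constant truth against a constant
clustering is defined as 0 with a warning.

## Synthetic data: what it emulates and what it does not

The generator plants a (modality, body part) group structure: procedural
images built from a group-specific base intensity (golden-ratio spacing
over the group index keeps distinct groups far apart), a modality-specific
gradient orientation and detector format, a body-part-specific geometric
primitive, and Gaussian noise (σ = 0.04 of the dynamic range by default);
tag tables with modality-correlated continuous tags, body-part-correlated
categoricals, an identifier, a constant, a free-text hint tag, a rarely
filled tag, and independent (MCAR) missingness at a configurable rate; BPE
blanked at a configurable rate with the body part recoverable from the
StudyDescription hint; and diagnoses drawn with Zipf weights from 30
body-part-specific stems plus 20 shared stems, with optional typo
corruption. `paired_groups=True` restricts each modality to one body part,
planting exactly five well-separated groups.

What passing tests show: every contract of the pipeline (shapes, ranges,
determinism, ordering, leakage discipline) and that the full system
recovers planted multimodal structure. What they do not show: performance
on real archives, whose missingness is informative rather than MCAR, whose
images differ by far subtler cues than the planted patterns, and whose
diagnosis language is unboundedly richer. Real-data metric values are
therefore out of scope here.

## Problem sizes and reduced configurations

Library defaults keep the full winning configuration (tag AE
512→200→125→32 at lr 1e-2; CAE 64/128/256/512+1024 at lr 1e-6 with PCA 500;
PV-DBOW 1,000 dims, window 7, 50 epochs, min frequency 50; concatenation
fusion; k-means Euclidean κ=50). `PipelineConfig.small()` is the package's
desk-scale configuration — CAE filters 8/8/16/16+32 at lr 1e-3 for 2
epochs, PCA 64, PV-DBOW 128 dims for 30 epochs with min frequency 5, tag AE
64→48→32→16, 25 imputation trees — chosen so that a full run on ~2,000
records completes in a few minutes on one CPU while leaving every
preprocessing step identical. The acceptance script and the end-to-end
tests use this configuration on 800 exams (~2,000 records) with 5 planted
groups and κ=5.

## Known limitations

* k-medoids materialises the full pairwise distance matrix (O(n²) memory);
  adequate for the tens of thousands of records the alternating heuristic
  is sensible for, not for millions.
* The imputation step is transductive (see above); strictly inductive
  operation would require persisting the fitted forests per column.
* The CAE and paragraph-vector models are plain numpy: correct and
  deterministic, but not competitive in speed with GPU frameworks at
  archive scale.
* Unseen-record assignment uses the nearest final centre in fused space;
  no rule is defined for records rejected by the image policies.
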