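# Methods

This note documents the models, parameter choices and numerical decisions
behind the `actfast` pipeline, and what the synthetic-data experiments do
and do not establish.

## The analysis model

The pipeline treats action perception as a decoding problem in a
six-dimensional conceptual action space (Abstraction, Creation, Tradition,
Food-relevance, Animacy, Spiritualism).  Its assumptions, stage by stage:

**Coordinates.**  Each action has one coordinate per dimension, obtained by
averaging per-rater ratings and z-scoring per dimension across actions
(sample SD, n−1).  Raters are assigned to exactly one dimension.  The
low-variability exclusion drops raters with ≤ 10 *unique rating values*;
an alternative reading (≤ 10 unique items answered) exists and is noted in
the exclusion report, but is not applied.  Missing (action, dimension)
coverage is an error, never imputed.

**Coordinate time series.**  At TR *t*, the stimulus location in action
space is the probability-weighted average of action coordinates,
`x_t = Σ_a w_{ta} c_a`, with annotation rows renormalized to sum to one so
each TR is a convex combination.  Renormalization makes the construction
invariant to the annotation's overall scale.  Coarse (e.g. 3 s) annotation
rows are upsampled to TR resolution by repetition.  Hemodynamic lag is a
fixed whole-TR shift (default 3 TRs at 1.5 s); the overhanging TRs at both
ends are dropped.

**Voxel selection.**  For each voxel, a per-action response profile is the
probability-weighted mean activity per action.  Cross-participant
consistency of the profile is Cronbach's α with *participants as items*
and actions as observations (`α = k/(k−1)·(1 − Σ_i σ²_i/σ²_total)`); the
transposed orientation is available via `items="actions"` since the
convention is a genuine judgment call.  The α values are split by a
two-component 1-D Gaussian mixture (EM, k-means init, tol 1e-6, ≤ 500
iterations), fit on the *sorted* values so selection is invariant to voxel
order; assignment is posterior argmax and the higher-mean component is the
action-sensitive set.  Collapsed components raise a dedicated error rather
than silently thresholding.

**Decoding.**  Six independent PLS regressions (scikit-learn, `scale=False`)
map selected voxels to the six coordinate series.  The only
hyperparameter, the number of latent components, is chosen per dimension
by nested split-half cross-validation: the training TRs are cut into two
*contiguous* temporal halves (a random TR split would leak autocorrelated
signal between halves), each candidate count is fit on one half and scored
by Pearson correlation of its predictions on the other, scores averaged
over both directions, ties going to the smaller count.  The chosen count
is refit on all training TRs.  `max_components` defaults to 20 in
`PipelineConfig`; the bundled synthetic experiments cap it at 8 because
the planted space is exactly six-dimensional, so 8 spans the truth with
headroom while keeping the search proportionate to the simulated problem
size.

**Reference coordinates and alignment.**  Ranking anchors are *decoded*
coordinates: the probability-weighted time-average of the decoded training
TRs per action (a fixed point of the construction when decoding is perfect
and annotations one-hot).  Group anchors are computed from the stacked
training participants; the held-out participant's own anchors come from
applying the same trained model to *their training-section TRs*.  A
Procrustes similarity transform (orthogonal rotation + isotropic scale +
translation, least squares; rotation-only available via
`procrustes_scaling=False`) maps group anchors into the participant's
space.  Actions with zero annotation mass in training get no anchor and
are excluded from the candidate list.

**Prediction and inference.**  Each test discrete action — a maximal run
of TRs sharing the argmax annotation, ties to the lowest action index,
segmented within one cross-validation section so runs never span section
boundaries — is summarized by the unweighted mean of its decoded TRs and
ranked against all candidate anchors by Euclidean distance (optionally
restricted to one dimension).  Top-k accuracy at lag L asks whether the
true action of run *i+L* appears in the first k of run *i*'s lag-0
ranking; future runs are never decoded, so BOLD autocorrelation cannot
produce lag ≥ 1 accuracy.  Lag instances that overrun the section are
skipped, not wrapped.

The null permutes which action owns which reference row.  Because
distances are unchanged under relabeling, a permuted top-k set is the
preimage of the observed one, which makes the null exact and cheap.
Permutations are shared across folds (drawn once from the seed), so the
group-level null is the distribution of across-fold mean accuracies and
fold means are comparable per permutation.  P-values are one-tailed with
the +1 correction; ties with the observed value count toward the null
(conservative).  Per-participant p-values pool all folds in which that
participant was the test subject.  Bi-cross-validation enumerates every
(section × participant) pair by default (85 folds at the source study's
geometry of 5 sections × 17 participants; 20 on the reference synthetic
world).

## The synthetic generator

The generator emulates exactly the structure the analysis claims to
detect:

- action coordinates: i.i.d. Gaussian, z-scored per dimension;
- sequence: first action uniform, then `P(j|i) ∝ exp(−d(i,j)/τ)` over
  j ≠ i.  Softmax of negative distance is the minimal monotone law
  consistent with "closer means more likely to follow"; τ → 0 gives
  nearest-neighbour walks, τ = ∞ gives uniform transitions (the
  negative-control regime).  Self-transitions are excluded because
  discrete actions are defined as maximal runs — a self-transition is
  unobservable after run merging;
- run durations: 2 + Poisson(1) TRs at a 1.5 s TR, giving a ~4.5 s mean
  discrete action, matching naturalistic annotation statistics of a few
  seconds per action;
- annotations: the true action receives mass `concentration` per TR, the
  remainder is spread over other actions with random weights (rows sum to
  one).  This is a declared approximation: the error distribution of a
  real video annotator is not being modeled;
- voxels: reliable voxels carry a shared 6 → voxel linear map composed
  with a small participant-specific orthogonal rotation of the space
  (matrix exponential of a skew-symmetric perturbation, scale 0.1), plus
  Gaussian noise; the rotation means Procrustes alignment has a true
  solution to find.  Unreliable voxels are unit-variance noise.  Every
  voxel is z-scored over time, as in standard preprocessing;
- ratings: one dimension per rater, ~70 actions per rater assigned by
  shuffled round-robin (guaranteeing coverage), rating = coordinate +
  rater bias + noise on a 1–100 integer scale (the response scale is a
  package choice).  Planted degenerate raters answer from a 5-value
  palette to exercise the exclusion rule.

**Reference conditions** (used by the acceptance script, the heavier
tests, and the analysis drivers): 332 actions, 4 participants, 2,000 TRs,
200 voxels of which 100 reliable, τ = 0.3, concentration 0.6, voxel noise
SD 0.3.  These sizes keep a full 20-fold bi-cross-validated run with a
1,000-permutation null around 20 s on one CPU while preserving the
qualitative regime of the real design (hundreds of candidate actions, a
handful of participants, ~4.5 s discrete actions).

**What passing these experiments shows — and does not.**  The synthetic
world is linear, stationary, and free of head motion, physiological
confounds, annotator bias and scene structure; participants share one
voxel grid and differ only by a small rotation.  Success here establishes
that the *pipeline* is correct and leak-free (it recovers planted
structure, and its null is calibrated: the permutation mean sits at
k/n = 5/332 = 1.51%), not that any particular real dataset contains such
structure.  Absolute accuracies on synthetic data are far higher than
anything expected from real BOLD.

## Statistical calibration of the negative control

With uniform transitions, each lag ≥ 1 group accuracy is (approximately)
exchangeable with its permutation null, so any single lag falls inside the
null's central 95% interval with probability ≈ 0.95.  The package
therefore evaluates null-consistency *per lag across replicates* (each
lag should be inside in ≥ 18 of 20 replicates); demanding that all five
lags be jointly inside in 18 of 20 replicates would fail in expectation
(20 × 0.95⁵ ≈ 15.5) even for a perfectly calibrated pipeline.

## Numerical choices

- z-scoring uses the sample SD (ddof 1) everywhere; zero-spread columns
  are centered and left at zero rather than producing infinities.
- Argmax ties (segmentation, ranking) break to the lowest index; ranking
  uses a stable sort, so equal distances order by candidate index.
- PLS intercepts fold scikit-learn's internal feature centering into a
  plain affine map, so stored coefficients reproduce `predict` exactly.
- `fit_pls` rejects `max_components` above the centered feature rank, and
  correlation scores on constant predictions are treated as missing.
- Cronbach's α is NaN (flagged, never selected) when the total variance
  is zero; actions with a missing pattern in any participant are dropped
  from the α computation.
- Model/reference/transform content hashes round to 10 decimals before
  hashing so the leakage guard is insensitive to formatting, not to
  values.
- All generators and the pipeline are bit-reproducible given a seed;
  sub-seeds are spawned via `numpy.random.SeedSequence`.

## Known limitations

- The hemodynamic model is a fixed whole-TR shift; no HRF convolution.
- The 339 → 332 agent-variant merge list of the source annotator is not
  public, so variant merging takes a user-supplied map.
- The Procrustes target ("the participant's own representational space")
  is operationalized as the participant's training-TR decoded anchors;
  other definitions (e.g. voxel-level hyperalignment) are out of scope.
- Per-participant significance pools all folds where that participant is
  the test subject; with few sections this rests on few folds.
- The synthetic annotator error model (fixed concentration + random
  background) is a stand-in, not an inference about any real classifier.
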