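# Methods

## Model and procedure

A cohort is a set of pain drawings digitized on one shared body template.
The template fixes the raster geometry and a boolean inside-body mask; the
number of inside pixels `m` is the feature count of every vector.  (For
reference, the published study's printed template had 477,400 pixels of
which 134,270 lay inside the body outlines; these counts are documentation
of scale, not invariants of this package's synthetic templates.)

A drawing is binarized pixel-wise: marked iff the scanned intensity is
below a threshold (default 128, dark ink on white paper — the source data's
binarization rule is not recorded, so this default is our own) and the
pixel is inside the body; outside-body ink is clipped.  A drawing with no
marked pixel carries no information and is excluded by default, as blank
forms are in practice.

The pain profile of a group is the pixel-wise relative marking frequency
`x_i = (#drawings with y_i = 1)/n`.  Pooling several groups (e.g. all rare
diseases into one RARE group) overlaps the union of their drawings, so
larger groups inform the pooled profile more; this is intentional and
mirrors how a pooled reference would be built from the available data.

Classification uses the Ružička similarity `Σ min(x_i,y_i) / Σ max(x_i,y_i)`:

* k-disease rule: argmax of the raw similarities over the group profiles.
* binary rule: the two similarities are normalized to sum to 1 and the
  positive-group score `s = S_a/(S_a+S_b)` is compared to a threshold
  (default 0.5).  Normalization is monotone, so at 0.5 the binary rule and
  the two-class argmax agree except on exact ties.
* baselines: 1-nearest-neighbor drawing-vs-drawing under Ružička
  (= Jaccard) similarity, and kernel 1-NN under the induced distance
  `d_K = sqrt(K(x,x) − 2K(x,y) + K(y,y))` with a Gaussian kernel
  `exp(−‖x−y‖²/2σ²)` or a distance-reciprocal kernel `1/(1+‖x−y‖)`.
  Both induced distances increase strictly with the Euclidean distance, so
  their 1-NN predictions coincide with Euclidean 1-NN; the schemes are kept
  separate so reports name the classifier that was requested.

### Assumptions

* All drawings in a cohort are registered to the same template at the same
  resolution; no resampling, rotation or skew correction is attempted.
* Markings are binary presence/absence; pain intensity is not modeled.
* A group profile is an adequate summary of its class — multimodal classes
  (distinct pain-pattern subgroups) violate this and degrade sensitivity,
  which is why the generator can simulate subgroup mixtures.

## Evaluation

Leave-one-out cross-validation rebuilds only the held-out drawing's own
(possibly pooled) group profile from the group's remaining members; every
other group keeps its full membership.  This is the standard leakage-free
protocol for per-group reference profiles: each drawing is scored against
profiles it never contributed to, while the competing profiles use all the
information that would be available in deployment.  Any group contributing
to a profile must have at least two drawings.

* Confusion matrices: rows true, columns predicted; sensitivity
  `cm[c,c]/row_c`, specificity `TN_c/(total − row_c)`, accuracy
  `trace/total`.  Rates are kept at full precision; rounding (3 decimals or
  whole percent) happens only at presentation.
* ROC: cut-offs at every distinct score, predict positive iff score ≥
  cut-off.  AUC is the trapezoidal area, computed via midranks and equal to
  the Mann–Whitney probability with ties worth 1/2.  The 95 % CI uses the
  DeLong variance (midrank formulation) with a normal approximation,
  clipped to [0,1].  The optional per-threshold sensitivity band is a
  stratified bootstrap (positives and negatives resampled separately,
  default 2000 replicates, percentile 2.5/97.5, seeded).
* Youden threshold: the cut-off maximizing sens + spec − 1; ties resolved
  to the smallest cut-off.
* Better-than-random tests: two-sided Fisher exact for 2×2 confusion
  matrices (zero margin ⇒ p = 1 by convention), Pearson chi-square without
  continuity correction otherwise, with all-zero rows/columns dropped and a
  flag when any expected count is below 5.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `inside_threshold` | 128 | template intensity below which a pixel is inside the body |
| `mark_threshold` | 128 | scan intensity below which a pixel counts as marked |
| binary `threshold` | 0.5 | cut-off on the normalized positive score (dimensionless, in (0,1)) |
| Gaussian `sigma` | median pairwise training distance | kernel bandwidth in pixel-count units (‖·‖ over m binary features); the median heuristic is used because no bandwidth is prescribed for this task |
| `n_boot` | 2000 | bootstrap replicates for the sensitivity band |
| `background_noise` | 0.05 | per-region probability of a noise mark in the generator |

## Tie-breaking and degenerate inputs

Ties in any argmax/argmin are broken by canonical order (class order =
first appearance in the manifest; training order for neighbors) and
flagged, so counts are exactly reproducible.  The binary boundary `s =
threshold` predicts the positive class (≥ rule).  A drawing similar to no
profile (all raw similarities 0) has an undefined normalized score and is
flagged rather than silently scored; empty drawings cannot be classified
at all.  Profiles persisted as 16-bit PNGs quantize frequencies to
1/65535, so round-trips are exact to half that step.

## Synthetic data generator

The generator emulates the structure the classifiers assume: each class
marks named template regions independently with class-specific
probabilities (optionally a mixture of subgroup maps), plus a shared
background-noise probability per region; a marked region sets all its
pixels, giving drawings region-level spatial coherence.  The analytic
per-pixel marking probability is `p_i = 1 − (1 − p_class,i)(1 − noise)`.
By default each subject is conditioned on marking at least one region
(study inclusion criteria require the presence of pain, and exact class
sizes are needed for cross-validation); unconditional sampling is
available and is what matches the closed form exactly.

The bundled five-group spec mimics the published study design: classes
EDS/GBS/FSHD/PROMM/CP with sizes 59/29/35/89/50, one or two signature
regions per disease at probability ≈ 0.7 (e.g. spine/knees for EDS, feet
for GBS), shared regions at ≈ 0.5, a two-subgroup PROMM mixture
(thighs marked in 60 % of subjects at 0.85 vs 0.1 otherwise, giving the
reported ≈ 0.55 marginal), and a diffuse chronic-pain class with every
probability ≤ 0.4 (lower back highest).  Probabilities not fixed by the
study description (noise 0.05, subgroup weights 0.6/0.4, the CP
off-maximum values) were chosen once as plausible for scanned cohorts of
this kind.

What the generator does **not** emulate: anatomically shaped outlines,
pixel-level stroke texture, partial region shading, intensity grading,
scanning artifacts, or correlations between regions beyond class
membership.  Tests passing on synthetic cohorts therefore validate the
*machinery* (profiles, similarity, LOOCV protocol, ROC/test statistics),
not clinical performance on real drawings; the published AUCs are not
reproducible without the patient data and are deliberately not targets of
the test suite.

Seeding: one master seed; each subject's stream derives from
(seed, CRC-32 of the class label, subject index), so cohorts are
bit-stable under class subsetting and reordering.

## Problem sizes used in tests and the acceptance script

Synthetic templates are 32×32 (4 bands, m = 576) for unit/property tests
and 64×128 (12 bands, m = 4608) for the five-group cohort of 262 drawings.
Parameter recovery uses 2000 subjects (unconditional sampling, closed-form
check at 5000); the chance-level LOOCV check averages 200 seeded
replicates of two i.i.d. 30-drawing classes.  These sizes make every
statistical check's noise floor comfortably smaller than its tolerance.

## Known limitations

* Profile-based classification is sensitive to multimodal classes; the
  PROMM-style subgroup mixture in the generator demonstrates the
  degradation but the package offers no subgroup discovery.
* The "inverse" kernel has no single canonical definition; the
  `1/(1+d)` form implemented here is this package's documented choice.
* The DeLong CI uses a normal approximation and can be conservative near
  AUC = 1; the bootstrap band covers sensitivity only, not specificity.
* No registration: scans must already be pixel-aligned to the template.
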