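# Methods

This note records the models, parameter choices and numerical decisions
behind `cephaloc`, and what the synthetic experiments do and do not show.

## Model overview and assumptions

The system assumes a single skull per image, imaged laterally, with the
19-landmark configuration well approximated by a similarity-posed linear
shape model. Three learned components cooperate:

* a **global detector** (one regression forest on a pseudo-landmark at the
  reference-frame centre) that is scanned over scale/angle grids and votes
  into accumulators — robust to where and how large the skull appears;
* **per-landmark displacement-voting forests** operating on Haar features of
  patches in a pose-normalised reference frame;
* a **PCA point-distribution model** whose mode weights are hard-clamped at
  ±3 sd, fitted to the vote peaks by weighted alternating least squares.

Votes are unit-mass, one per tree per evaluated position, binned at 1 frame
px (the vote histogram reading of regression voting); no Gaussian spreading
or per-leaf weighting is applied.

## Key parameters

Stage configuration (`StageConfig`), all lengths in reference-frame px:

| parameter | full-resolution default | compact default | meaning |
|---|---|---|---|
| `frame_width` | coarse 100 / fine 500 | 50 / 120 | width of the pose-normalised frame |
| `ps` | 20 / 30 | 10 / 7 | sampled patch size |
| `tr` | ±15 / ±30 | ±7.5 / ±7.2 | training displacement range |
| `sr` | ±(1.0·pr+15) / ±(0.3·pr+7) | ±(1.0·pr+7.5) / ±(0.3·pr+1.7) | search-window half-width |
| `n_features` | 400 | 120–150 | Haar pool size per landmark |
| `n_trees` | 10 | 10 | trees per forest |
| `min_samples_leaf` | 10 | 10 | leaf granularity |

The refinement-stage full-resolution values are the improved settings for
isolated cephalometric landmarks (larger patches and training range, smaller
search range); the coarse stage keeps the original bone-contour settings.
The **compact** preset scales all lengths proportionally to its frame widths
(120/500 for the fine stage, 50/100 for the coarse) and is what the tests,
examples and the acceptance script use; frame width 500 on a 340×400 px
synthetic image would upsample ~4× without adding information. `pr` is the
per-landmark coordinate range (larger of x/y) over the aligned training
shapes, in the stage's frame px.

Patch sampling perturbs each training patch by a random scale in ±10% and
rotation in ±6° (appearance only — the displacement label is unchanged) for
robustness to pose-estimation error. Haar responses are divided by the patch
mean absolute intensity + 1e-6 for lighting robustness; the raw `haar_value`
operation stays linear in intensities, normalisation lives in the pool
evaluation layer.

Detector: scale grid ×1.25 steps (factors 0.7–1.4 of the median training
scale; 0.8/1.0/1.25 in the compact preset, whose generator varies scale by
±8%), angles −12°…+12° in 6° steps, scan stride 2 px, accumulator smoothed
with a box filter before peak picking, sub-cell peak refinement by local
vote-mass centroid. The detector initialises the search; residual error of a
few image px is absorbed by the coarse CLM stage, whose capture range
(±sr per landmark plus shape constraint) is an order of magnitude larger.

## Constrained optimisation

The vote-maximisation over {**b**, θ} is solved by a deterministic
alternating scheme: (1) per landmark, candidate = argmax of the 3×3
box-smoothed vote grid within a window of half-width `sr` around the current
estimate, ties broken at smallest y then x; (2) weighted `fit_params`
(weights = smoothed vote mass at the candidates; clamp applied every solve);
(3) repeat until the model points move < 0.5 frame px, at most 5 rounds.
Bounded per-point residuals (`residual_limit`, 3 frame px) toward the vote
peaks are applied at the end, so the output can deviate slightly from the
pure model shape while still satisfying the clamp when re-fitted. On a
rigid (zero-mode) model this scheme reproduces brute-force search over a
coarse pose grid (tested).

`fit_params` itself alternates the closed-form weighted similarity fit with
the clamped linear solve for **b**, to 1e-9 max point movement or 50
iterations — tight enough that generated shapes are recovered to 1e-6 in
both mode weights and pose.

## Early stopping

After each iteration's vote casting, every landmark's vote spread — the
mass-weighted mean distance of its votes from their centroid — is converted
to refinement-frame px via the ratio of the stages' frame scales; the stage
loop exits once all spreads are ≤ 4 (the `early_stop_threshold`). The check
runs in both stages. In the compact configuration the fine stage typically
converges below threshold in its first iteration, while the coarse stage's
wide original-style windows keep spreads above it, so with the default
10 + 1 schedule early stopping changes the output only when extra fine
iterations are configured — where it saves those rounds at < 1 frame px
output difference.

## Synthetic data: what it emulates, and what it does not

`SyntheticSpec` defaults: 340×400 px at 0.4 mm/px, template rendered at
2.4 px/unit (object ≈ 90 mm wide), pose uniform in ±10 px translation,
0.92–1.08 scale, ±6° rotation; three orthonormal shape modes (jaw rotation,
lower-face height, anterior protrusion; sd 2.2/1.5/1.0 units); Gaussian
noise sd 0.02 on a [0, 1] intensity scale. The renderer draws only
structures a radiograph would show: smooth (Catmull-Rom) contours for the
mandible, maxilla, orbit, cranial-base ridge, incisor axes and soft-tissue
profile; blobs for the sella and ear canal. Landmark difficulty is emulated
by (i) most landmarks lying at gentle curvature extrema rather than at
distinctive local features, (ii) a duplicated posterior mandibular border at
a patient-specific random offset of 2–9 units (imperfectly superposed
left/right outlines), and (iii) three random clutter arcs (overlapping
projected structures). Each case derives from a counter-based RNG keyed by
(seed, index), so datasets are bit-reproducible and order-independent.

The generator does **not** reproduce radiographic texture (trabecular bone,
scatter fog, soft-tissue gradients), pathology, age-related variation, or
the full inter-patient shape variability of a clinical population. Passing
the synthetic end-to-end tests therefore demonstrates the machinery —
detection, voting, constrained search, classification, statistics — not
clinical-grade accuracy; mm-level results on real cephalograms require
training on real annotated data through the same interfaces.

One finding from the synthetic comparison experiments: with desk-scale
training budgets (50 images, ~1000 patches per landmark), refinement-stage
error is dominated by the forests' leaf spatial granularity, which grows
with the training range `tr`. Under these conditions the small-context
original settings (ps 20, tr ±15, wide search) outperform the
larger-context/decreased-search settings on the clean synthetic ridges —
the opposite of the ordering on real radiographs, where local appearance
ambiguity dominates and larger context pays off. The corresponding
comparison test documents this as an expected failure of the synthetic
conditions to reproduce that real-data effect.

## Numerical choices and degenerate inputs

* Coordinates are 0-based, origin at the top-left pixel centre, y downward;
  annotations are stored at 3-decimal precision, spacing in config.
* Resampling is bilinear with nearest-edge padding; frames carry a padding
  margin `pad = ps/2·1.1·√2 + max(tr, sr_max) + 3` so boundary landmarks
  keep full windows.
* PCA keeps the smallest mode count capturing 98% of variance; zero-variance
  training sets give a rigid (0-mode) model, handled throughout.
* `angle_between_lines` returns the acute form min(φ, 180°−φ); ODI/APDI are
  sums of unsigned angles as printed in the clinical definitions.
* Class boundaries: the named closed range owns its endpoints (ANB 3.2 and
  5.7 → C1); >/< classes are strict; MW = 0 exactly → C2, with sign(0) = 0.
  The MW sign follows image x (rightward); a flag flips it for left-facing
  images.
* SDR counts the boundary as a success (error ≤ z).
* Tree training is delegated to scikit-learn's regression trees
  (deterministic under a fixed `random_state`); trained trees are flattened
  to arrays for vectorised voting and canonical serialisation, and the model
  archive is a fixed-timestamp, sorted, uncompressed zip so identical models
  are identical bytes.
* Votes landing outside a window grid are dropped but counted, preserving
  the vote-mass ledger (mass + dropped = trees × positions).

## Problem sizes used by tests and the acceptance script

Training 50 synthetic cases / testing 20, compact preset; the
parameter-settings comparison trains two refinement stages at frame width
500 on the same 50/20 split; the cross-validation and CLI tests use 6–12
images with reduced pool/sample counts. These sizes were chosen so the whole
suite runs in minutes on one CPU while every component is exercised
end-to-end.

## Known limitations

* Single-object images only; no multi-skull handling beyond returning
  lower-ranked detection candidates.
* The two-stage schedule is fixed at two resolutions; no deeper pyramids.
* The optimiser is a deterministic surrogate (argmax + weighted LS) for the
  joint vote-maximisation; it is validated against brute force on rigid
  instances but is not guaranteed globally optimal with active shape modes.
* Classification inherits landmark error nonlinearly near class boundaries;
  narrow-ranged parameters (e.g. ANB classes ~2.5° wide) flip classes with
  ~1 mm landmark error, as the confusion matrices on synthetic data show.
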