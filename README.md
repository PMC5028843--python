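# cephaloc

Fully automatic localisation of cephalometric landmarks in lateral skull
radiographs, and automatic classification of the skeletal malformations
derived from them.

Cephalometric tracing — marking anatomical points such as the sella, nasion
and gonion on a lateral cephalogram — underpins orthodontic diagnosis and
treatment planning, but doing it by hand is slow and inconsistent within and
across clinicians. `cephaloc` implements a fully automatic annotation
pipeline for the standard 19-landmark set, the eight clinical measurements
built on those landmarks (ANB, SNB, SNA, ODI, APDI, FHI, FMA, modified
Wits), and the agreement statistics used to evaluate such systems. It is
aimed at medical-image-analysis researchers and at orthodontic software
developers who need a reproducible, trainable baseline.

## Method

The pipeline is **Random-Forest regression-voting in a Constrained Local
Model framework (RFRV-CLM)**, applied coarse-to-fine:

1. **Global detection.** A regression forest is trained on a single
   *pseudo-landmark* — the centre of a reference frame enclosing all 19
   points. Slid across the image at a grid of scales and orientations, every
   tree at every window position votes for the frame centre in an
   accumulator array (Hough-style); the strongest smoothed peak gives the
   skull's position, scale and rotation, and the mean shape mapped through
   that pose initialises the landmarks.
2. **Local voting.** Per landmark *l*, a forest maps Haar features **f**(**x**)
   of patches (computed in O(1) from integral images) to the displacement
   from the patch centre to the landmark. Casting one vote per tree over a
   search window of half-width *sr* = *a*·*pr* + *c* — where *pr* is the
   landmark's positional range over the aligned training data — accumulates
   a vote histogram **V**_l.
3. **Shape constraint.** A PCA point-distribution model built from
   Procrustes-aligned training shapes expresses each landmark as
   **x**_l = *T*_θ( x̄_l + (**P** **b**)_l + **r**_l ), with mode weights
   clamped to |b_j| ≤ 3√λ_j. Pose θ and weights **b** are fitted to the vote
   peaks (weighted by vote mass) by alternating least squares, maximising
   the votes collected over all 19 points.
4. **Coarse-to-fine schedule.** Ten iterations at a low-resolution reference
   frame, then refinement at high resolution. The refinement stage uses the
   settings found best for isolated cephalometric landmarks — patch size 30,
   training range ±30, decreased search range ±(0.3·*pr* + 7) at frame
   width 500 — while the coarse stage keeps the original bone-contour
   settings. An early-stop rule ends a stage once every landmark's votes
   agree to within 4 refinement-frame px on average; the search is fully
   deterministic, so the same image always yields the same annotation.

The located landmarks feed eight clinical measurements (Table-style class
boundaries, e.g. ANB: C1 3.2–5.7°, C2 > 5.7°, C3 < 3.2°), and the evaluation
module computes point-to-point errors (PE/PEL/PEI ± SE), successful
detection rates (SDR at 2.0/2.5/3.0/4.0 mm), CDFs of image errors, and
successful classification rates (SCR) with confusion matrices.

Because the clinical dataset such systems are trained on is not bundled, the
package ships a **synthetic-data generator**: a tuned 19-point template
deformed by known shape modes, posed by a random similarity transform, and
rendered with smooth bone/soft-tissue contours, a duplicated mandibular
border at a patient-specific offset, clutter arcs from overlapping
structures, and noise. Every module is therefore trainable and testable
end-to-end with exact ground truth.

## Worked example

```bash
python examples/02_train_and_locate.py
```

trains the compact configuration on 30 synthetic cases and searches a
held-out image:

```
stages run: [('coarse', 10), ('fine', 1)] (iterations per stage; early stop ends a
stage once every landmark's votes agree to within the threshold)
mean point-to-point error: 1.02 mm (max 2.84 mm) — distance between located and
true landmark positions
worst landmark: L14 (lower lip), 2.84 mm
```

The mean error is the PEI of that image: the average distance, in mm at the
synthetic 0.4 mm/px spacing, between located and true landmark positions.
`examples/03_clinical_report.py` prints the eight clinical parameters of the
template subject (all in the normal class C1), and
`examples/04_evaluate_agreement.py` shows the evaluation statistics.

The same pipeline is available from the shell:

```bash
cephaloc synth --n 20 --seed 1 --out data/
cephaloc train --data data/ --out model.bin --seed 1 --spacing 0.4
cephaloc search --model model.bin --data data/ --out auto/ --spacing 0.4
cephaloc classify --data auto/ --glob '*.auto.txt' --out report.csv --spacing 0.4
cephaloc evaluate --manual data/ --auto auto/ --auto-glob '*.auto.txt' \
    --out eval/ --spacing 0.4
```

Real cephalograms (TIFF at 0.1 mm/px with 19-line `x,y` annotation files)
go through the same commands with `--preset full`.

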