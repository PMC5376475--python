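# Methods

This note documents the models behind `phaseflow`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Problem and model

A surgical workflow of a fixed surgery type runs through Q named phases in a
fixed order with no backtracking. The observable is motion: in each phase,
staff, instruments and materials move in characteristic regions of each
camera's view. The pipeline therefore models the phase process as a
left-to-right Markov chain observed through quantized motion features:

* **Motion words.** Flow vectors between consecutive smoothed frames are
  filtered to the magnitude band [ǒ, ô] px and quantized to four directions
  on a spatial grid. A word = (camera, cell, direction). Two extraction
  variants trade coverage for cost: `GridIntersect` samples one point per
  cell; `GridBlock` pools all foreground pixels per block and requires at
  least ö survivors before averaging, which denoises but touches far more
  pixels.
* **LDA.** The words of one second form a document; LDA with symmetric
  priors α = 50/K (document–topic) and β = 0.1 (topic–word) summarizes it as
  a K-simplex mixture θᵢ. Topics capture co-occurring flows — e.g. "many
  rightward flows in the upper-left of camera 0 together with downward flows
  in camera 1" — which single words cannot.
* **Normalization.** The HMM observes one categorical symbol per second:
  `top` takes argmax θᵢ (alphabet K); `kmeans` assigns θᵢ to the nearest of
  c codebook centers fitted on training features (alphabet c). k-means can
  merge seconds whose θ differ in argmax but are close in the simplex, which
  is why it tends to outscore `top` (visible in `examples/03`).
* **Left-to-right HMM.** Transitions allow only q→q and q→q+1, the last
  state is absorbing, and π puts all mass on phase 1. Supervised
  initialization counts transitions (T_{q,q} = N_{q→q}/N_{q→·}) and
  per-state symbol frequencies from labeled training workflows; Baum–Welch
  then refines on the same symbol sequences, pooling expected counts across
  sequences. Viterbi decoding yields monotone per-second labels.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| blur kernel | 7×7 | Gaussian smoothing before differencing and flow; σ = 0.3·((k−1)/2 − 1) + 0.8, the conventional size-matched width |
| diff_threshold | 15 / 255 | frame-difference binarization; no principled value exists for generic scenes, so it is exposed in config. Lower values admit more noise pixels; the magnitude filter downstream removes most of the consequences |
| grid | 64×48 | 10×10 px cells on 640×480 frames; scale it with frame size (tests use 16×12 on 160×120) |
| ǒ, ô | 2, 20 px | flow magnitude band, inclusive on both ends; kills sensor jitter (<2) and wrap/occlusion artifacts (>20) |
| ö | 5 | minimum surviving flows per block in `GridBlock` |
| K | 20 | LDA topics; α = 50/K, β = 0.1 |
| c | 230 | k-means clusters at full scale; c ≤ n is required, so small corpora need proportionally smaller c |
| ε | 10⁻⁴ | emission smoothing |
| Baum–Welch | tol 10⁻⁴, ≤ 100 iter | on total log-likelihood |

## Numerical and design decisions

* **Grid intersection points.** "One point per cell" is realized at each
  cell's top-left corner — all grid-line crossings except the right and
  bottom frame borders. This keeps a clean bijection between points and
  cells (interior-only crossings would give (cells_x−1)·(cells_y−1) points
  and orphan the last row/column of the word vocabulary).
* **Direction ties.** |dx| = |dy| resolves to the vertical axis; zero
  vectors are rejected (callers filter by magnitude first). Determinism of
  quantization matters more than the particular choice.
* **Emission smoothing.** The raw ratio count/(N_q + ε) leaves unseen
  symbols at exactly 0, which makes held-out decoding fail on any novel
  symbol. Every cell is therefore floored at ε and rows renormalized. During
  Baum–Welch the floor is *not* applied inside the EM loop — that would
  break the monotone-likelihood guarantee — but once after convergence.
* **Left-to-right zeros under EM.** A zero transition accumulates zero
  expected count, so the structure is preserved by the update itself; no
  masking is needed. The absorbing last row is reasserted against round-off.
* **LDA inference.** Mean-field variational Bayes (scikit-learn's batch
  implementation), deterministic given the seed. Train-time features are
  produced by folding each document in with the fitted topics — the same
  operation applied to test documents — so train and test features go
  through an identical code path. Empty seconds (no words) receive a
  uniform θ, flagged, keeping the per-second timeline aligned with the
  annotations rather than introducing a dedicated null symbol.
* **k-means.** Lloyd's algorithm with greedy farthest-point seeding
  (deterministic: start from the point farthest from the data mean, then
  repeatedly add the point maximizing distance to its nearest seed) and
  farthest-point re-seeding of empty clusters. Plain Euclidean distance on
  the simplex, as in the objective. The per-assignment inertia trace is
  recorded and is nonincreasing.
* **Decoder.** Viterbi in log space is the default; a forward-filtering
  argmax is available behind `decoder="forward"`. Note the filtering argmax
  is *not* guaranteed monotone — the filtered marginal can momentarily
  favour an earlier state — whereas Viterbi paths are monotone by
  construction.
* **Fold pooling.** In cross-validation, Baum–Welch refines one model per
  fold on all of that fold's training sequences jointly (summed expected
  counts), not per workflow.
* **Metric edge cases.** Seconds predicted wrongly are charged to the true
  phase's denominator only; a phase the decoder never emits scores 0
  accuracy and NaN boundary deviation ("undetected"). The trailing partial
  second of a recording is dropped everywhere (documents, labels,
  annotations), keeping all per-second timelines the same length.

## Synthetic data

`synthetic.py` generates phase-scripted recordings with exact ground truth.
Each phase renders a fixed random blocky texture patch drifting at constant
speed in a phase-specific direction inside a phase-specific region of each
camera (direction cycle rotated per camera), over a static background with
additive Gaussian pixel noise. The patch wraps inside its region; the single
wrap-frame displacement exceeds ô and is filtered out. The factory
`make_dataset()` mirrors a participants × recordings × cameras design
(default 7 × 4 × 3 = 84 streams).

Default synthetic scale is deliberately below the nominal recording setup
(160×120 px at 5 fps, 12 phases of 6–10 s, blob speed 3 px/frame) so that a
full leave-one-out evaluation of three workflows completes in minutes on one
core; the grid scales accordingly (16×12 keeps 10×10 px cells), and c must
shrink to respect c ≤ n (~200 training seconds per fold).

What the generator emulates: phase-distinctive motion direction and
location, multiple viewpoints that disagree on apparent direction, pixel
noise, variable phase durations. What it does not: articulated human motion,
several simultaneous actors, lighting changes, occlusion, camera shake,
phases distinguished by motion *speed* or *texture* rather than
direction/place. Passing end-to-end tests therefore demonstrates that the
pipeline correctly propagates genuinely phase-discriminative motion into
phase labels; it does not certify accuracy on real operating-room footage,
where the discriminative signal is weaker and noisier.

The symbol-mode generator (`make_left_to_right_hmm`,
`generate_symbol_sequences`) samples directly from a known left-to-right
model with geometric state durations (self-transition 1 − 1/mean_duration)
and per-state emission rows concentrated on distinct dominant symbols. It
isolates the estimator stack from the vision stack: parameter-recovery
results quantify the HMM machinery alone.

## Known limitations

* Optical flow comes from a dense iterative Lucas–Kanade field sampled at
  the requested points; very large displacements (fast motion at low frame
  rates) exceed its convergence basin and fall out through the magnitude
  filter.
* Variational LDA finds local optima; degenerate corpora (e.g. K = V with
  one word type per document) may need a different α or a restart to
  separate all topics. Seeds make every fit reproducible.
* The left-to-right assumption is structural: a workflow that genuinely
  revisits a phase cannot be represented.
* `PhaseAnnotation` requires every phase 1..Q present exactly once and
  contiguous; partially observed workflows are supported only as prefixes
  (phases 1..k).
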