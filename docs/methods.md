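# Methods

This note documents the models and procedures implemented in `synrec`,
the defaults and why they are set where they are, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Tiling

Large EM sections are covered by a minimal grid of square tiles: per axis
of length `D`, `max(1, ceil((D − overlap)/(tile − overlap)))` tiles at
stride `tile − overlap`, with the last anchor clamped to `D − tile` so
every tile lies inside the image. An image no larger than one tile gets a
single tile clipped to the image. This rule guarantees full pixel
coverage and at least `overlap` pixels of overlap between adjacent tiles
(more for the clamped last tile). Detections are *not* clipped when
mapped back to section coordinates; partial boxes from straddling
synapses are left for fusion to merge.

Defaults: 1000 px tiles for large anisotropic sections, 500 px for
smaller isotropic ones, 50 px overlap — roughly half a synapse's long
axis at the respective pixel sizes, enough that no synapse is entirely
split without being seen whole (or half-seen twice) somewhere.

## Detection

The detector is a contract, not a model: any callable mapping a grayscale
tile to `[(box, score), ...]` plugs in, and external detections can be
injected from CSV/JSON. The bundled baseline is a classical dark-ridge
detector (adaptive binarization of pixels darker than the local mean,
3×3 opening, connected components filtered by area 60–5000 px and
elongation ≥ 2, bounding box padded 5 px, score = normalized mean
darkness). Its defaults were tuned against the synthetic generator only;
it exists to exercise the pipeline, not to compete with a learned
detector on real EM.

## Fusion

Within one section, boxes are duplicates if their centers lie within the
fusion distance ϑ. The relation is closed transitively (single-link),
each group is replaced by its coordinate envelope, and the group's
maximum score is kept — envelope and max-score preserve both the spatial
extent and the ranking used by AP evaluation. Grouping by transitive
closure in a single pass makes the result deterministic and independent
of input order, unlike greedy pairwise merging. One documented
consequence: an envelope's center can move relative to its members, so a
second pass over the output may occasionally merge further; fusion is
defined as a single pass and tested as such.

ϑ defaults: 100 px at 2 nm/px, 50 px at 5 nm/px — about half the long
axis of a synapse, the farthest apart two detections of the same object
plausibly sit (e.g. a partial box at a tile border against the full box).

## z-continuity screening

A box in section `i` is kept iff at least `L` of the `2L − 1` sections
`i − (L−1) … i + (L−1)` contain a box whose center is within υ of its
center. A section contributes at most 1 regardless of how many nearby
boxes it holds (the count is over layers), and the box's own section
always counts. Windows are clipped at the stack faces rather than
discarding boundary sections, so a synapse touching the first or last
section can still be kept when supported from one side.

Monotonicity: keeping is monotone in υ unconditionally (more support can
only be gained). It is monotone in `L` for contiguous support — the
physical regime, where a kept box is equivalent to its track spanning ≥ L
sections — but *not* for arbitrary gapped support, because raising L also
widens the window: a box supported only at `{i−2, i, i+2}` is kept at
L = 3 yet removed at L = 2. The test suite asserts the L-monotonicity on
contiguous-track volumes and the υ-monotonicity on arbitrary ones.

Kept boxes are linked into tracks by greedy nearest-center chaining
between nearby sections (a gap of one missing section is allowed to
heal), ties broken toward smaller x then y; tracks are numbered in order
of first section, then x, then y. Linking is deliberately simple — tracks
feed 3-D export and statistics, and optimal multi-object tracking is out
of scope.

Defaults: L = 3, υ = 200 px for 50 nm-thick sections (a ~400 nm synapse
crosses 3+ sections); L = 20, υ = 100 px for 5 nm isotropic ones.

## Cleft segmentation

Stage by stage, per kept box (cropped with 10 px of context):

* **Adaptive binarization**: foreground = pixels darker than the local
  mean (51 px block) minus an offset of 10 intensity units; the block is
  shrunk for small patches. Clefts are dark by convention throughout.
* **Morphological opening** (3×3 elliptical element, 1 iteration)
  removes speckle.
* **Quadratic fit**: `m = max(3, round(W/3))` foreground pixels (W =
  foreground count) are sampled uniformly without replacement and
  `y = ax² + bx + c` is fit by least squares. Degenerate inputs: < 3
  foreground pixels aborts the fit and the morphological mask is returned
  directly (logged fallback); < 3 distinct x-columns (a vertical cleft)
  yields the flat curve through the mean and defers to the endpoint
  fallback.
* **Endpoints**: the foreground pixels nearest the curve at the minimum
  and maximum foreground x. If all foreground sits in one column the
  endpoints fall back to the min/max-row pixels — clefts inside detection
  boxes are predominantly transverse, and the fallback guards rotated
  ones.
* **Shortest path**: Dijkstra on the 8-connected grid where stepping onto
  pixel q costs `intensity(q)/max + ε` (ε = 0.01, diagonals scaled √2).
  Intensity weighting is what makes the geodesic trace the dark cleft; an
  unweighted path would cut straight across. ε keeps costs positive so
  the search terminates on bright patches too.
* **Trimap**: path pixels (their own skeleton) are sure-foreground; the
  pixels outside the detection box, plus `0.1 × box area` random in-box
  pixels farther than 8 px from the path, are sure-background; the rest
  is unknown. If the stand-off leaves no candidates (tiny boxes) it is
  halved until some exist.
* **GrabCut**: per-class K = 5 component Gaussian mixtures (grayscale
  features, so the full covariances degenerate to scalar variances,
  regularized by +1e-6; the code path is written for general
  dimensionality), T_G = 10 iterations of (i) per-pixel best-component
  assignment within the current class, (ii) closed-form ML refit of both
  mixtures, (iii) exact minimization over the labeling by an s-t min-cut
  (igraph) with the data term on terminal links and the canonical
  contrast-sensitive smoothness
  `S = γ Σ [βₘ ≠ βₙ] dist(m,n)⁻¹ exp(−β̂ (αₘ − αₙ)²)`,
  `β̂ = 1/(2⟨(αₘ − αₙ)²⟩)`, γ = 50, on the 8-neighbor links. Seeds are
  hard constraints (infinite terminal capacity). The energy recorded
  after each iteration is non-increasing by construction of this
  coordinate descent, and the suite asserts it on every run.

  Two choices were genuinely open. First, the initial labeling: unknown
  pixels start as *background* and the foreground mixture is fit from the
  path seeds alone. (The classic initialization labels the whole unknown
  region foreground; with a thin path seed that would smear the
  foreground model across both intensity modes and can make the first
  cut degenerate.) Second, component assignment runs inside every
  iteration, not once — each iteration improves the mixture parameters.
* **Component filter**: only output components touched by the seed path
  are kept, suppressing detached dark debris inside the box.

All stochastic stages (point sampling, background seeds) draw from one
per-patch seed derived from `(global seed, section, box index)`, so runs
are bitwise reproducible.

## Evaluation

The 70% overlap criterion is interpreted as intersection-over-union
(the community default); intersection-over-truth is exposed as
`overlap_kind="iot"` for the alternative reading. Matching is greedy in
descending score with one-to-one constraint — for detection geometries
(disjoint truths, each prediction overlapping at most one truth above
threshold) this equals the optimal assignment, and the suite checks it
against a Hungarian oracle on such instances. AP is the raw step integral
of precision over recall, without 11-point or monotone interpolation.
With no predictions retained, precision is undefined and reported as 1 at
recall 0.

Dilation for the k-pixel-tolerant metrics uses a 3×3 square element per
pixel step (uniform 1-px boundary growth); `jaccard_k` reduces exactly to
the plain Jaccard at k = 0, and k-pixel precision/recall/AP dilate both
prediction and truth masks before matching.

## Synthetic generator

Each planted synapse is a quadratic ribbon — matching the segmentation
model's own assumption that cleft shapes are near-parabolic, with an
optional cubic perturbation flag for probing beyond it — rendered at the
cleft intensity across 3–6 consecutive sections with ≤ 2 px per-section
jitter. Defaults (the study conditions for all end-to-end tests):
768×768×12 px volumes, 4 synapses of length 100–200 px (≈ 400 nm at
2 nm/px), thickness 4–8 px, |curvature| ≤ 0.004, cleft intensity 60 on a
background of 160 with Gaussian noise (sd 10) and low-frequency texture;
4 single-section distractors shaped like short ribbons so the baseline
detector sees them and the z-continuity screen — not the detector's shape
filter — is what removes them. Object centers keep ≥ 160 px separation
(twice the screening υ = 80 used at this scale), making distractors
unambiguous screening fodder. The screening/fusion preset for this
geometry (ϑ = 100, L = 3, υ = 80) scales the full-size EM defaults to the
~10× smaller canvas, with ϑ kept at the synapse-extent scale because tile
duplicates of a 200 px object can sit ~100 px apart.

A box-level generator shares the same geometric plans and emits jittered
true boxes, near-duplicates (≤ 20 px offset), and far-away single-section
false boxes with per-box labels, so fusion and screening are tested in
milliseconds without rendering.

What the generator does **not** emulate: membranes, vesicles and other
organelles (the textured background is far cleaner than neuropil),
section-to-section registration error beyond small jitter, anisotropic
PSF, staining variability, or touching/branching clefts. Consequently the
near-perfect end-to-end scores on synthetic volumes demonstrate the
correctness of the pipeline's logic — duplicate fusion, continuity
screening, seed placement, energy minimization — not the accuracy
achievable on real EM, which is detector-limited and texture-limited.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
768×768×12 synthetic volumes (5 seeds end-to-end), 20×20 patches for the
shortest-path oracle (100 instances), 200 random sections for the fusion
oracle, 50 random box volumes for the screening oracle. All randomness is
seeded; the acceptance script derives every stream from its `--seed`
argument.

## Known limitations

* Fusion is single-pass; pathological box clusters whose envelopes
  converge can require a second pass (documented and tested behaviour).
* Track linking is greedy and local; crossing synapses closer than υ in
  adjacent sections could be mis-linked.
* The baseline detector is shape-based and will miss low-contrast or
  blob-like synapses on real data; it is a stand-in for a learned
  detector, not a replacement.
* Registration of raw section stacks is out of scope; input stacks are
  assumed aligned.
* GrabCut runs on grayscale features; color/multi-channel EM is not
  supported.
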