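# Methods

## Dichromacy simulation

The simulation models complete dichromacy — total absence of one cone class —
not anomalous trichromacy; there is no severity interpolation. The pipeline
for a condition other than `none` is

```
sRGB → (IEC 61966-2-1 decode) → linear RGB → LMS → projection → LMS
     → linear RGB → clip to [0,1] → (encode) → sRGB
```

**Color spaces.** Linear RGB → LMS is the Hunt–Pointer–Estevez cone matrix
composed with the sRGB→XYZ (D65) matrix, then row-normalized so that linear
RGB white (1,1,1) maps to LMS (1,1,1). Working in this normalization makes
the neutral (gray) axis the vector (1,1,1) in LMS, which simplifies both the
construction and the tests.

**Projection construction.** A dichromat's perceptual surface is modeled as
plane(s) through the origin containing the neutral axis:

- *Protanopia / deuteranopia*: one plane through the neutral axis and the
  575 nm spectral anchor, projected along the missing cone axis (L or M).
  This is the single-plane reduction of the two half-plane construction,
  justified because the 475 nm and 575 nm anchor planes nearly coincide for
  these conditions.
- *Tritanopia*: two half-planes hinged on the neutral axis, anchored at
  660 nm (reddish side) and 485 nm (bluish side), projected along S. A pixel
  belongs to the reddish half-plane iff its LMS vector lies on the
  non-negative side of the plane spanned by the neutral axis and the S axis
  (normal = white × e_S); the tie set (dot product exactly zero) goes to the
  first (660 nm) half-plane — a deterministic tie-break on a measure-zero
  set.

Anchor LMS directions are CIE 1931 2° color-matching values at
475/485/575/660 nm pushed through the same normalized matrix chain, so the
whole construction lives in one consistent space. Each projection
`P = I − e nᵀ/(n·e)` is exactly idempotent with rank 2, fixes the neutral
axis, and maps the pixel cloud onto a plane (two hinged planes for tritan).
These exact properties are what the test suite asserts.

The projection planes pass through *monitor white* rather than the
equal-energy stimulus. This is the standard adaptation when simulating on an
sRGB display: it guarantees achromatic ramps are preserved to within
floating-point error, at the cost of a slight rotation relative to a strictly
equal-energy construction.

**Alternate model.** The Machado et al. (2009) severity-1.0 matrices are
available (`model="machado"`); they operate directly in linear RGB, preserve
the gray axis (rows sum to 1), but are not idempotent projections, so the
geometric invariants above are asserted for the default model only.

**Gamut and quantization.** Out-of-gamut values after projection are hard
clipped in linear RGB — the simplest deterministic policy. 8-bit files
decode as value/255 and re-encode as round(value·255); outputs are always
PNG so repeated simulation is bit-stable. In memory the simulation is a
fixed point to 1e-6 on unclipped pixels; through two file round-trips a
deviation of one 8-bit quantum (1/255) is possible and is the tolerance the
tests use.

## Synthetic fixtures

The generator emulates only what the downstream task needs: a balanced
two-class set of lesion-on-skin images whose class-conditional *color*
distributions differ.

- Background: jittered flat skin tone (mean sRGB (0.86, 0.70, 0.62)).
- Melanoma: ellipse with irregular radial boundary perturbation (a crude
  asymmetry cue), filled with Voronoi patches drawn from a four-color
  palette — red, dark brown, black, blue-gray — with Dirichlet(4,3,2,1)
  mixing weights, biased toward red.
- Nevus: smooth ellipse, single color interpolated between light brown and
  pink, mild radial shading.
- Additive Gaussian noise (sd 0.02 in sRGB) clipped to gamut.

Defaults are 50 images per class at 128×128 px with a fixed generator seed —
a balanced n = 100 design at desk scale. Generation is a pure function of
(spec, seed): every image uses the child stream
`SeedSequence([seed, class_index, image_index])`, so runs are bit-identical.

Class separation is summarized as *red dominance*, mean(R − (G+B)/2) over
the central lesion region; the melanoma-minus-nevus gap must exceed a
configured margin (default 0.04; the default set measures ≈ 0.057). Red
dominance rather than the raw red channel is used because dark melanomas
have a *lower* raw R than pale pink nevi even when they are far redder in
hue.

What the fixtures do **not** emulate: dermoscopic texture (networks,
globules, vessels), hair and rulers, illumination gradients, camera noise
statistics, or any histopathologic ground-truth ambiguity. Passing tests
therefore demonstrate that the pipeline's mechanics and statistics are
correct, not that any backend generalizes to real dermoscopy.

## Few-shot protocol

References are sampled uniformly without replacement, leave-one-out, k per
class (default 2). The sampling stream is seeded by the replicate seed
(`base_seed + replicate`) mixed with a CRC of the query id, so one replicate
seed gives every query an independent but reproducible draw, and two runs
sharing `base_seed` (the ablation arms) sample identical reference
*identities*.

The prompt is a versioned text template instructing: compare the query with
the labeled references, pick the most similar, answer with one class word,
then explain the color features used. References appear melanoma-first, each
class in sampled order, query last. The request digest hashes template
version, text, and all image bytes; it keys response caches and resumability.

Answer parsing: `clean` when the first word is a class keyword
(melanoma/malignant vs nevus/benign), `recovered` when exactly one class is
mentioned elsewhere, `failed` when none or both without a leading answer.
Failed parses are excluded from accuracy denominators and vote counts but
always reported — silent imputation would bias accuracy.

**Mock backend.** Implements the instructed rule literally: feature = mean
linear-RGB color of the central lesion disk (radius 0.35·min(H,W); fixtures
center their lesions, so the disk is an adequate operational lesion region),
distance = Euclidean; an 8-bin-per-channel histogram-intersection mode is
available. Ties go to the first minimal reference, i.e. to melanoma under
the fixed presentation order. The explanation names the modal hue word
(red/pink/brown/blue/gray by hue-angle, saturation and value bands) over
lesion pixels, which is what gives the mining analysis real signal.

## Experiment statistics

- Per-repeat accuracy over parse-scoreable predictions; summary is mean and
  *population* sd (ddof 0) across repeats — the sd convention is documented
  because error bars are otherwise ambiguous; a single repeat has sd 0.
- Consensus: melanoma iff melanoma votes ≥ threshold (default 5 of 10); "at
  least" means a vote count exactly at threshold is melanoma. The rule is
  monotone in the vote count (tested exhaustively).
- Confusion counts treat melanoma as the positive class.
- Ablation arms share `base_seed`; the matched arm simulates references to
  the query's condition, the control leaves them non-simulated. The reported
  effect is the signed difference in mean per-repeat accuracy. Whether a
  real study would share sampling draws across *conditions* is a design
  choice; here seeds are shared within an ablation pair only.

## Explanation mining

Grouping is per (image, replicate) prediction: RED if any token stems to
"red" (red, reds, redder, reddest, reddish; hyphenated compounds split, so
"red-brown" counts), else PINK for pink stems, else NEITHER. Matching is
whole-token, so "infrared" is not a red mention. Negated mentions ("no red
areas") still count as mentions — a known simplification. The keyword lists
are arguments, so other lexicons can be swapped in.

Group rates are 100 × (melanoma predictions / group members) per replicate;
replicates where a group is empty are missing, never zero. Groups are
compared with a two-tailed two-sample t-test, Welch by default (pooled
variance available via flag) — the unequal-variance form is the safer
default when group sizes differ by construction. Degenerate zero-variance
pairs report p = 1 (equal means) or p = 0 (different), flagged explicitly. A
seeded permutation test (10⁴ permutations) is provided as an independent
cross-check of the parametric p-value.

## Problem sizes and determinism

The canonical in-repo study is 100 fixtures × 10 repeats × k = 2 with the
mock backend; a full run (baseline + three matched conditions + three
ablation pairs + mining) completes in well under a minute on one CPU because
image features and simulated PNG bytes are cached per (image, condition).
All randomness flows from named integer seeds; prediction logs and reports
contain no timestamps, so identical invocations are byte-identical.

## Known limitations

- The dichromat model is display-referred sRGB only; no ICC color
  management, no anomalous-trichromacy severities, no daltonization.
- The central-disk lesion region is a fixture-specific operational choice;
  real dermoscopy would need segmentation.
- The mock backend is a color nearest-neighbor — deliberately simple so its
  behavior is exhaustively checkable; it is a test instrument, not a
  claim about how a vision–language model classifies.
- Real-API backends (OpenAI-compatible) are provided behind the same
  contract but are unexercised by the offline suite.
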