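# Methods

This note records the models behind `micropat`, the parameter choices that
matter, and what the synthetic validation does and does not demonstrate.

## Geometry and the canonical frame

Patterns are parametric: discs (radius *r*), ellipses (semi-axes *a* ≥ *b*),
hollow ellipses (an outer ellipse minus a strictly smaller inner one) and
four-petal flowers (four ellipses with radial major axes around a common
centre). Every statistic is computed in a *canonical frame* — shape centre
at the origin, major axis along +x — reached by a rigid transform
(translation + rotation), which makes registration explicit and testable:
pairwise distances are preserved to machine precision and the patterning
score is invariant under any rigid placement of the colony.

Default dimensions are reverse-engineered from the published,
mutually consistent distance pairs rather than taken from a drawing:
a 97.5 µm disc radius makes "62.7 µm from the centre" equal "34.8 µm from
the boundary", and a 120 µm semi-major axis makes "109 µm from the centre"
equal "11 µm from the tip"; the ellipse minor semi-axis 79.58 µm then
fixes the area at ~30,000 µm². The large ellipse is the same aspect ratio
scaled to 90,000 µm²; the hollow ellipse is the large outline with the
inner ellipse at half scale. All are overridable.

Point-to-ellipse distance has no closed form; it is solved by bounded
scalar minimisation of the squared distance over the boundary parameter
(folded into the first quadrant, three bracket restarts plus the quadrant
endpoints), validated against a 10⁶-point dense-sampling oracle to
≤0.05 µm. Disc distances are exact. *Travel distance* is planar even when
z is carried, because its normaliser (disc radius / semi-major axis) is a
planar length; points beyond it simply exceed 100%.

## The patterning score and classification

`score = log₂(mean travel% of T⁺ cells / mean travel% of all cells)`, with
"all" including the T⁺ cells (the verbatim rule). The score is undefined
when a colony has no T⁺ cells (category *none*).

Classification supports two rules for *undefined* (random positioning):

- **sign rule** (default in the API): undefined iff score ≤ 0;
- **permutation rule** (recommended, used in the validation experiments):
  additionally require a one-sided permutation test (1,000 random
  same-size subsets of the travel distances; p ≤ 0.05) to reject random
  positioning.

The permutation rule is preferred because "undefined" *means* "randomly
positioned", and under the sign rule a truly random colony lands on the
patterned side of zero half the time by chance; the test makes the
category match its definition. Patterned ellipse colonies are *two-sided*
iff each major-axis side holds ≥25% of the T⁺ cells (threshold
configurable; no quantitative rule is published); patterned discs have no
sidedness and are reported as `patterned`.

## The synthetic-experiment generator

The generator reproduces the statistical structure of the reference 48 h
micropattern experiments; all randomness flows from one integer seed via
`numpy.random.SeedSequence`, so identical configurations give
byte-identical tables.

- **Growth.** Poisson seed count (mean 27) grown exponentially with a 12 h
  doubling time until confluency at 24 h (≈110 cells per colony), then a
  24 h doubling time — two phases because confluent colonies slow down;
  this yields ≈220 cells at 48 h, the size used throughout validation.
- **Positions.** Rejection sampling inside the shape with a radially
  thinned acceptance `1 − 0.6ρ²` (ρ = normalised elliptical radius),
  emulating dome-shaped colonies densest at the centre, plus a 6 µm
  hard-core separation (nuclear exclusion) enforced by dart throwing.
- **T⁺ fractions.** Per-colony fraction drawn from a normal truncated to
  [0, 100] with the reported means ± SDs (12.6 ± 5.2% discs,
  17.1 ± 7.5% ellipses). Only mean ± SD are reported, and truncation
  keeps fractions valid.
- **Spatial bias.** T⁺ count k ~ Binomial(n, fraction); k cells are drawn
  without replacement with probability proportional to
  `(1−β)·1 + β·w(x)`, β the bias strength and *w* a mode weight decaying
  exponentially with distance to the nearest tip (tips), to the boundary
  (periphery/border) or to the centre (central; decay ¼ of the semi-major
  axis). One-sided modes mask the tip weight to one side. Bias is
  *label assignment*, not cell movement: the pipeline observes endpoints
  only and the underlying sorting-versus-induction mechanism is an open
  question, so the generator stays agnostic.
- **Tip decay length: 10 µm.** T⁺ cells are reported averaging 11 µm
  from the tip. Under label assignment on dome-sampled positions the mean
  tip distance of 17% of cells cannot go below ~31 µm (the nearest-to-tip
  cells simply occupy more room than that), so the decay is set at nucleus
  scale — the tightest localisation the model family expresses — rather
  than fitted. This is the one place the generator knowingly understates
  the real effect; consumers of mean-tip-distance statistics should not
  read generated values as data-like.
- **Category mixture.** Two-sided 35% and one-sided 40% of all ellipse
  colonies, with 85% of T⁺-containing colonies patterned; these three
  reported proportions jointly imply 13.2% randomly positioned
  ("undefined", simulated at bias 0) and 11.8% zero-T⁺ ("none") colonies,
  which is the default split.
- **Intensities.** Log-normal per channel: one component for the nuclear
  stain (mode 500 AFU, 0.10 log₁₀ spread) and two for brachyury (modes
  100/1000 AFU, 0.15 log₁₀) — a well-separated quantitative-IF mixture
  (≈6.7σ), so gating error is a per-mille effect and fraction-recovery
  experiments measure the pipeline, not the gate.
- **Time and treatments.** Spatial bias is zero before a 36 h ramp
  (patterning emerges after confluency). Treatment presets rescale the
  fraction and override the mode: Wnt inhibition (IWP2) → ¼ fraction,
  central; Nodal inhibition (SB) → ¼ fraction, random; Fgf inhibition
  (PD17) → unchanged fraction, border-restricted.

## Image quantification

Rendering and segmentation are 2D at 0.38 µm/px (the reference lateral
sampling; its 3D stacks are out of scope, and every downstream statistic
is planar). Cells are stamped as 3 µm-radius discs carrying their channel
intensities, blurred with a 0.5 µm Gaussian PSF, over Gaussian background
noise (10 ± 2 AFU). Segmentation is the standard chain — 1 µm Gaussian
smoothing, Otsu threshold, distance-transform watershed seeded at maxima
≥3 µm apart, ≥9 µm² size filter — with a robust-MAD guard that returns an
empty result instead of Otsu-splitting pure background. Centroids are
nuclear-intensity-weighted (sub-pixel); per-channel means are taken over
each object mask. On rendered ~110–250-cell colonies this recovers ≥95%
of ground-truth cells one-to-one within 2 µm and reproduces truth-table
patterning scores to ≤0.1; there is no manual-correction stage, and the
front end is validated only against synthetic truth, not against stained
tissue.

## Binned density maps

A BDM pools registered cells of one class into a fixed grid (default
10 µm ≈ one cell diameter) covering the canonical bounding box; fractions
are per pooled cell (counts sum exactly to the pooled total), not per bin
area, and partial edge bins are reported as-is with an interior-bin mask
available for occupancy statistics. No symmetry folding is applied:
one-sided colonies keep their generated side, so pooled ellipse maps show
both tips even when individual colonies are polarised — matching how
pooled maps look in practice. Flower petals register with the inner tip
(nearest the flower centre) at −x, flipping by 180° when needed.

## Other numerical choices

- Neighbour counts are planar by default ("a circular region"), self
  excluded, with boundary distances counting as neighbours; a 3D metric is
  available. Counts are exact (k-d tree, verified against the O(n²)
  oracle).
- The density regression uses log₁₀ density as covariate (tested densities
  span 25×), OLS with the standard pointwise 95% band; linear covariate
  configurable.
- Flower tip windows are the outer quarter of the major axis on each end
  (|x| ≥ a/2 at the default 0.25); the inner/outer log₂ ratio uses a
  pseudo-count of one cell's worth of percentage, and a petal with zero
  T⁺ cells at both tips reports ratio 0.
- Pfaffl ratios require amplification efficiencies > 1; ΔCt is
  Ct(control) − Ct(sample).
- Gating falls back from the mixture model to a fixed threshold only when
  the fitted components are within 0.1 log₁₀ units; with no fallback it
  raises rather than guessing.

## Validation scales and limitations

The validation experiments use 300 colonies for the score null
calibration (mean |score| ≤ 0.05), 500 colonies per condition for
fraction and classification recovery, 1,000 replicates for regression CI
coverage, and single rendered colonies of ~110–250 cells for
segmentation — sizes at which the binomial/CLT standard errors sit
comfortably inside the stated tolerances while a full run stays in the
tens of seconds.

What passing does *not* show: the generator's phenomenology (exponential
tip weights, truncated-normal fractions, log-normal intensities, two-phase
growth) is a statistical stand-in, not a mechanism; real images have
uneven illumination, z-blur and touching-nucleus pathologies the renderer
omits; and the saturation of the one-sided tip weight at high T⁺ fractions
(a ~35%-T⁺ one-sided colony cannot place all its T⁺ cells "at" one tip)
bounds per-colony scores in a way real spatial reorganisation need not.
Results on real feature tables depend on upstream segmentation and gating
quality that this package can check only against its own synthetic truth.
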