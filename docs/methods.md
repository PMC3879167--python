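# Methods

## The assay being modelled

A CPRG indicator screen reads envelope integrity out as colony colour: an
intact envelope excludes the chromogenic substrate, so colonies of intact
mutants stay white, while lysing or permeable mutants cleave CPRG and turn
pink to red, with the red product diffusing outward as a halo. Plates carry
an ordered library in a pinned grid (16×24 = 384 positions by default,
32×48 = 1536 supported), each mutant present as two replicate clones, and
are photographed at two incubation times: near the end of vegetative growth
and again about seven hours later (defaults 12 h and 19 h). Colour
development is proportional to incubation time, but halos widen with it, so
quantification prefers the early image.

## Synthetic forward model

`synthetic.render_plate` renders a plate as discs at jittered grid
positions on a background with a linear intensity gradient, a quadratic
vignette, and i.i.d. Gaussian sensor noise, quantized to 8-bit sRGB.

**Colour.** A colony with pigment level `r` ("redness", dimensionless, 0
for white) is rendered at hue 0° with saturation

    s(r) = 0.95 · (1 − e^(−r))

on a colony body of HSV value 0.95. The map is linear in `r` for faint
colonies and saturates for deep red ones, mimicking pigment optical
density; it is strictly increasing, which the tests rely on. The halo
carries a rim fraction (0.5) of the colony pigment with Gaussian radial
decay of width `σ = halo_diffusion_sigma_per_hour · t`. The default rate
of 0.25 px/h was fixed by the assay's own premise: at the early default
timepoint a red colony's spill into an adjacent cell stays below ~2% of its
own score, while at the late timepoint spill onto neighbors is strong
enough to create false hits — the behaviour the early-timepoint rule
exists to avoid. Halo width scales linearly with time (per the
colour ∝ time observation); colony radius does **not** grow between
timepoints, deliberately isolating colour effects from size effects.

**Screen truth.** `design_screen` plants CPRG+ mutants at a per-condition
fraction of 2% by default. With `specific_fraction = 0.75` (default) the
positive union is structured so ~75% of positive mutants are positive in
exactly one condition and the rest in all conditions, emulating the mostly
condition-specific hit structure of a multi-condition screen; with
`specific_fraction = None` each condition is planted independently
(Binomial planting). Positive effect sizes (redness accrued per hour) are
log-uniform on [0.01, 0.15], chosen so the faintest positive colony's
chroma at the early timepoint (s ≈ 0.11) sits ~5× above the sensor-noise
chroma floor (≈0.02 at noise sd 0.01) — i.e. planted positives are
*visibly* pink, as a screener would require — while the strongest approach
full red. Two clones per mutant sit at separate positions of the same
plate by default (`arrangement="sister_plates"` puts them at the same
position of two sister plates; how the two library clones are physically
arrayed is not standardised, so both are supported).

**Colony sizes (GI).** `simulate_colony_sizes` draws
`size = base · fitness · interaction · LN_plate · LN_colony` with mean-one
log-normal factors (`exp(N(−σ²/2, σ²))`). Mean-one noise makes the
expected growth score of a neutral gene exactly 1 and the empirical mean
size converge to `base_size`; a plain `exp(N(0, σ²))` factor would bias
both upward by `e^(σ²/2)`, which contradicts the model's own neutrality
requirement. Defaults: plate effect sd 0.2, colony noise sd 0.1, 4
replicates.

All randomness flows from integer seeds through numpy's splittable
generator; per-plate substreams derive from (seed, condition index, plate
index), so identical seeds reproduce every image bit for bit.

## Quantification

**Grid fit** (`fit_grid`): the value channel (max of RGB) is
background-subtracted with a large Gaussian; colonies project as periodic
peaks onto each axis. An optional small-angle rotation search (±2°, on a
downsampled image) maximizes projection sharpness; then each axis gets a
comb fit — spacing estimated from the profile autocorrelation, offset and
spacing refined by maximizing interpolated profile mass over the comb —
followed by per-line sub-pixel centroid refinement. The grid is rigid
(evenly spaced lines + global rotation, no per-row warp), as pinning robots
produce; the RMS deviation of refined lines from the comb is reported as
`residual` so violations are detectable. Failure (unplaceable comb,
non-monotone centers) raises `GridFitError` carrying the profile. On
synthetic 384-pin plates with colony jitter sd 3 px the fitted lines land
within ~0.5 px of the true lattice (the projection averages jitter over a
full row/column).

**Segmentation** (`segment_colony`): within each cell (rectangle of one
pin spacing around the grid node), foreground is the value-channel
deviation from the cell's border-annulus background above an Otsu split;
the connected component at the cell center is kept; components below
`min_area` (12 px²) come back flagged `empty`. Segmentation uses the value
channel, not redness, so red colonies are not systematically larger or
smaller by construction. The halo annulus is the agar of the cell within
`0.5 × pin spacing` of the colony rim.

**Redness score** (`measure_color`, `cprg_score`): per-pixel redness is
saturation times a Gaussian kernel on circular hue distance from h_ref = 0°
with σ_h = 20°; the score is the sum of `max(0, w − w_bg)` over colony plus
halo (halo inclusion is the default and can be disabled). The exact scoring
formula of the original screen's software was never published; this
definition was chosen because it is zero-calibrated on white colonies,
extensive (scores span orders of magnitude when effect sizes do), and
verifiable per-pixel against an independent implementation.

`w_bg` is a robust *envelope* of agar redness — mean + 2 sd of the
per-pixel redness over the plate frame outside the grid, the one region
colony halos cannot reach. Two failure modes dictated this choice: the
redness of a single median agar colour ignores sensor-noise chroma, which
then accumulates over the ~10³ pixels of a colony-plus-halo region into a
noise floor comparable to faint colonies; and per-cell border annuli are
tinted by the colony's own halo, which would cancel exactly the signal
being measured. The envelope is exactly 0 on noiseless images, so white
plates score exactly 0. When the grid leaves no frame (< 200 px), the
median over cells of border-annulus redness statistics is used instead.

**Neighbor contamination** (`flag_neighbor_contamination`): halo redness is
accumulated by quadrant (N/S/E/W of the colony centroid). A colony is
flagged when an 8-neighbor scores above the hit threshold *and* above the
colony's own score (spill flows from redder to whiter positions) and the
colony's halo redness facing that neighbor exceeds γ = 1.5 times the
opposite side plus an absolute floor of 5% of the threshold. A second pass
keeps only flags whose contaminating neighbor survived the first pass, so
a single red colony flags its ring of neighbors but the flags do not
cascade outward. The own-score condition matters: without it, a genuinely
red colony whose own halo is slightly asymmetric can be "explained away"
by one of its spill-lit neighbors and dropped as a source.

## Screen statistics

- **Timepoint selection**: the earliest image at which ≥ 90% of expected
  colonies segment with area ≥ `min_area`; falls back to the last with a
  warning. (In the synthetic model geometry is shared across timepoints, so
  the earliest image always qualifies — which is exactly the assay's
  preference.)
- **Replicate averaging**: arithmetic mean of clone scores per mutant per
  condition; clones flagged `empty` or `neighbor_contaminated` are dropped
  first, mutants reduced to one clone are flagged `single_clone`, to none
  `no_clones` (missing score, never a hit). Averaging over whatever clones
  remain is deliberate: library dropouts are inevitable and a missing clone
  should not delete a mutant.
- **Threshold**: hits are `S > τ`, strictly (ties at τ are not hits). The
  historical cut-off 10^3.7 units is instrument-specific and kept available
  verbatim (`PAPER_THRESHOLD`, CLI `--threshold`); the default calibration
  τ = expm1(mean + 6·sd of log1p(S) over the central 90% quantile mass)
  places the threshold far out in the white-colony tail so that only a
  small proportion of mutants score positively. Raw scores are
  thresholded by default; per-plate median normalization is available but
  off.
- **Condition comparison**: all 2^k − 1 Venn membership classes;
  "condition-specific" means hit in exactly one condition; the fraction is
  over the union of hits.
- **Enrichment**: hypergeometric upper tail per term
  (`p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)` via `scipy.stats.hypergeom.sf`),
  Benjamini–Hochberg across tested terms (statsmodels); terms with fewer
  than 3 annotated universe genes are skipped. The universe defaults to
  the mutants actually quantified — the screen's sampling frame — not the
  whole genome. No GO DAG propagation is attempted; the annotation is a
  flat user-supplied gene→term table.

## Growth scores

`g = mean(grown replicate sizes) / mean(grown library clone sizes)`, the
library mean taken over all grown (size > 0) double-mutant clones of the
same plate set (optionally excluding border rows/columns, which overgrow
in pinned arrays). Dead replicates leave the numerator; all-dead genes
score 0 and are flagged `lethal-candidate`; dead clones also leave the
library mean so lethal combinations do not depress the reference.
Per-plate normalization (divide by each plate's library mean before
pooling) removes plate effects and is recommended whenever plate effects
exist. Classification uses a neutral band: suppressive above 1 + ε,
negative below 1 − ε, ε = 0.2 by default because a strict >1/<1 rule
classifies pure noise; ε = 0 restores the strict rule. Because "the
library average" and "the matched single mutant" are different baselines,
both reference modes exist (`library-mean` default, `matched-single` with
user-supplied per-gene reference sizes); the discrepancy between the two
definitions is inherent to the assay description and is surfaced rather
than resolved.

A note on recovery accuracy: with a planted interaction among G library
genes, the library mean itself contains the planted gene, so the expected
estimate is `1.9 · G/(G − 1 + 1.9)` (≈ 1.88 at G = 100), slightly below
the planted value; the recovery checks compare the *mean over 20 seeds*
against the planted value within ±0.15, which absorbs both this correction
and the per-seed sampling noise (sd ≈ 0.1 at 4 replicates).

## What the benchmarks show — and what they do not

The synthetic generator provides exact ground truth, so the test suite can
measure grid accuracy (mean pin-center error vs the analytic lattice),
score validity (zero on white plates; strict monotonicity in pigment;
Spearman rank recovery ≥ 0.98 on a 384-colony plate at default sensor
noise with fixed colony radius — the score is extensive, so radius scatter
is a real, size-driven variance source that the rank check deliberately
controls for), planted-hit sensitivity/specificity, the early-vs-late
timepoint logic, and growth-score recovery.

The generator does *not* emulate several features of real plate
photographs: specular reflections and condensation, non-circular or fused
colonies, agar cracks, colour cross-talk of real camera sensors, spatial
growth gradients, or plate-to-plate illumination differences beyond a
fixed gradient/vignette. Passing these benchmarks therefore demonstrates
the correctness of the algorithms under the stated model, not robustness
to arbitrary real-world imaging artifacts; the grid residual, segmentation
flags and diagnostic overlays exist so such violations are visible on real
data.

Problem sizes in the acceptance script were chosen to exercise the
screen-scale regime while staying comfortably reproducible on a single
CPU: 20 plates for grid recovery, 5 seeds × 384 mutants for hit recovery,
and one image-based 3968-mutant, 4-condition screen (21 plates per
condition, early timepoint) planted at the historically reported
per-condition hit rate (~150/3968 with 75% condition specificity), whose
recovered per-condition hit counts and condition-specific fraction are
reported as computed.

## Numerical choices and degenerate inputs

- Hue is circular throughout (circular distance for the kernel,
  saturation-weighted circular mean for `mean_hue`); achromatic regions
  (s ≤ 0.02) report `mean_hue = NaN` and redness 0.
- 8-bit quantization bounds colour resolution at ~0.4% of full scale;
  monotonicity checks use pigment steps ≥ 0.1 for this reason.
- Empty cells, all-dead genes, all-white plates, missing clones and
  single-timepoint series all take defined non-raising paths (flags,
  zero scores, trivial selection); hard errors are reserved for structural
  problems (duplicate layout positions, out-of-range indices, truths
  outside the grid, hits outside the enrichment universe, dead library
  reference, non-increasing timepoints).
- Grid cells at the image border are clipped; overlapping rendered discs
  warn and max-blend.
- Scores are deterministic functions of the image; all simulation
  randomness is seed-derived, and two runs with the same seed agree
  bit for bit.
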