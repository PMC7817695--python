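# Methods

This note documents the models, conventions and numerical choices behind
`jointphen`, what the synthetic generators do and do not emulate, and the
known limitations.

## Joint-surface-replica damage quantitation (`jointphen.jsr`)

The pipeline reproduces a semi-automated macro chain for quantifying
cartilage surface damage in SEM images of surface casts.  The standard
geometry is a 1536 × 1536 px image over an 1800 × 1800 µm field, giving
1.3733 µm²/px; the bright-outlier cutoff of 4 px is 5.49 µm² and the
damage-particle cutoff of 20 px is 27.47 µm² (the commonly quoted 5.5 and
27.5 µm²).

Conventions and defaults:

- **Coordinates** are row-major, origin top-left, 0-based.  Components are
  8-connected.
- **Manual protocol steps become explicit inputs.**  Plateau selection is
  a polygon (default: full frame), debris erasure a mask (default: empty),
  and the threshold either a manual gray value or Otsu (default).
  Provenance in `DamageQuantResult` records which mode ran.
- **Bright-outlier removal**: candidate pixels exceed their 5 × 5 local
  median by `brightness_delta` (default 2 × the scaled MAD of the image
  gray levels); candidate components of area < 4 px are replaced by the
  local median.  The 4-px cutoff is strict, so a 4-px speckle survives.
- **Edge detection** uses the unnormalized 3 × 3 Sobel kernels, so an
  ideal step of height h responds with magnitude 4h beside the edge;
  magnitudes are clipped to the image bit depth.
- **Automated threshold floor**: in Otsu mode the threshold is floored at
  median + 10 × MAD of the plateau edge magnitudes.  Otsu always splits a
  distribution, even a unimodal one; on a crack-free textured surface the
  upper tail of smooth texture gradients would otherwise be read as
  damage.  The floor is far below any real crack edge (which responds at
  4 × the crack depth) and is ignored in manual mode.
- **Particle measurement**: holes inside a component are filled before
  measuring, as the bench particle tool counts a crack outline with its
  enclosed area.  Edge detection of a crack of width w yields its outline;
  after filling, the recovered area is ≈ (w + 2)(L + 2) for a w × L crack
  — about one pixel of halo per side, which keeps recovery within ±15% for
  realistic crack widths.  Perimeters are measured as the length of the
  outer iso-contour (straight steps 1, diagonal steps √2); circularity
  4πA/P² is capped at 1.0.
- **Filters are strict inequalities** (area > 20 px; plateau components
  > 100 px), matching the "particle size > N" convention.
- A subtlety of the monotonicity property (lowering a manual threshold
  never decreases damage area): this holds for the size filter alone;
  with the circularity filter a growing particle can in principle cross
  the 0.5 boundary and drop out.  Crack-like particles at realistic
  thresholds stay far below 0.5.

## Microradiography densitometry (`jointphen.xrm`)

Calibration stretches raw grays linearly between the plastic standard
(bin 0) and the steel standard (bin 255):
bin = ⌊255·(g − plastic)/(steel − plastic) + 0.5⌋ clipped to [0, 255]
(round-half-up; the aluminum standard present in the physical images is
not used).  Standard levels are inputs — in practice the median gray of
operator-marked patches; automatic standard detection is out of scope.

The subchondral ROI is round-half-up(0.09 w) px tall and
round-half-up(0.34 w) px wide, where w is the tibial width at the growth
plate; its top edge sits at the topmost pixel at or above
`bone_bin_threshold` within the plateau's column range.  The default
threshold of bin 48 corresponds to the boundary of the lowest band of the
16-colour display lookup (3 × 256/16), i.e. the first clearly mineralized
band; it is configurable and recorded.

Relative BMC is the median calibrated bin: the smallest bin at which the
cumulative pixel count reaches half the ROI ("reaches 50%" read as ≥ 0.5,
so a 50/50 split of bins {0, 255} gives bin 0).  Only relative BMC is
produced; no absolute mineral mass calibration.

## Contrast-enhanced µCT morphometry (`jointphen.ct`)

Arrays are (z, y, x) = (proximal→distal, anterior→posterior,
medial→lateral).  Volumes are Gaussian-filtered (σ = 0.8 voxels, support
1 voxel, i.e. truncation radius 1) before segmentation.

**VOI scaling.**  Each VOI is 14% of the medial–lateral axis wide and 33%
of the anterior–posterior axis deep, centered medially–laterally on its
plateau midpoint; the lateral VOI is additionally shifted 7% of the ML
axis toward medial.  AP midpoints sit at 61.5% (medial) and 68.5%
(lateral) of the AP axis.  The two stated 7% offsets (ML shift of the
lateral VOI; 7% posterior shift of its AP midpoint) are implemented as two
separate displacements, as stated.  Landmark determination (rotating the
tibia into standard position, marking extents and plateau edges) is
manual upstream; landmarks are explicit inputs here.

**Segmentation.**  Cartilage: voxels < 200 mg HA/cm³ in the VOI; keep the
5 largest 26-connected components; close with a 5-voxel ball.  Bone:
voxels > 300 mg HA/cm³ in the slab between the cartilage base and the
growth plate; keep the 20 largest components; close with a 3-voxel ball.
"Dilation/erosion" is read as morphological closing with a discrete ball
of the stated radius, computed on a padded crop so the structuring element
is never clipped.  Retained cartilage components must additionally reach
within one closing-radius of the *shallowest* low-density voxel in the
VOI: the articular cartilage is the topmost soft structure under the
contrast bath, while deeper low-density pockets (unperfused marrow,
growth-plate cartilage) are rejected.  Thresholds always apply to density
units, never raw gray.

**Metrics.**  Cg.V = voxel count × voxel volume.  Thickness uses the
maximal-inscribed-sphere method: th(x) = 2·max{dt(c) : |x − c| ≤ dt(c)}
with dt the Euclidean distance transform; sphere radii are processed in
descending bins of max(0.25, r_max/40) voxels (floor-quantized, so
painted radii never exceed the true distance), which keeps the field
within one voxel layer of a brute-force sphere search.  Tb.Th is the mean
thickness of the bone phase; Tb.Sp the mean thickness of the background
within the compartment; Tb.N (direct, model-independent) = 1/(Tb.Th +
Tb.Sp), the reciprocal mean mid-axis spacing; the plate-model alternative
BV/TV / Tb.Th is exposed via `tb_n_method="plate"`.  TMD is the mean of
the *unfiltered* densities over bone voxels — Gaussian filtration mixes
boundary voxels toward marrow and would bias the mean low.  Metrics are
computed on the VOI crop: a structure clipped by a VOI face physically
continues beyond it, so crop edges are treated as continuations rather
than surfaces.

Because the contrast agent systematically raises apparent subchondral
density, all outputs are relative measures for within-study comparison;
absolute agreement with scanner software is not claimed.

## The screen (`jointphen.screening`)

- **Reference ranges**: Shapiro–Wilk at α = 0.05 (unstated upstream; fixed
  here) decides the branch — mean ± 2.0 SD (sample SD, n − 1) for normal
  parameters, 2.5th–97.5th percentiles with linear interpolation (type-7)
  otherwise.  A line is a range outlier when its mean falls strictly
  outside.
- **Wilcoxon rank-sum**: exact null distribution when the smaller sample
  has ≤ 10 observations and the pooled sample is tie-free; otherwise the
  normal approximation with tie and continuity corrections.  The switch
  point is configurable.
- **Effective number of tests**: N_eff = N − Σ_λ I(λ > 1)(λ − 1) over the
  eigenvalues of the reference parameter correlation matrix; the screen
  threshold is α/N_eff, with a second stringent threshold of 10⁻⁴ that
  additionally corrects for the number of lines screened.  With the
  reference correlation structure of the original 100-animal cohort
  (N_eff = 8.8) the operating threshold is P < 0.00568; synthetic cohorts
  yield their own N_eff.
- **MVE-robust Mahalanobis**: h = ⌊(n + p + 1)/2⌋ (floor).  The search
  draws seeded random elemental (p + 1)-subsets (default budget 10,000;
  exhaustive enumeration for n ≤ 20), expands each to its h nearest points
  and minimizes the ellipsoid volume.  The raw estimate (mean/covariance
  of the best h-subset, median-matched to the χ² median) is refined by one
  reweighting step: the classical mean and covariance of the points inside
  the χ²₍ₚ;₀.₉₇₅₎ cutoff, with two consistency factors — the truncation
  factor 0.975/P(χ²₍ₚ₊₂₎ ≤ q) and the finite-sample factor
  (m−1)(m+1)/(m(m−p−2)) that calibrates the χ² cutoff for observations
  outside the m-point fitting sample (whose squared distances follow a
  scaled F).  Without these, the raw MVE scatter flags far more than the
  nominal 2.5% of clean data.  Flags are MD² > χ²₍ₚ;₀.₉₇₅₎ and a line is
  called when ≥ 50% of its animals are flagged (2 of 4 counts).  At
  p = 18 with a 100-animal reference, the χ² cutoff remains somewhat
  anticonservative per animal (the F tail is heavier, and skewed
  parameters inflate distances); the ≥ 50% line rule keeps line-level
  false positives at the few-percent level.  A QQ diagnostic of ordered
  reference MD² against χ² quantiles is emitted with each screen.
- **Severity**: one point per criterion met (≤ 3) plus one per abnormal
  category (≤ 3).  The parameter→category map (not tabulated upstream):
  cartilage morphology = {Cg.V, Median Cg.Th, Max Cg.Th}; cartilage
  integrity = {Cg. Damage Area}; subchondral structure = {SC BV/TV, Tb.Th,
  Tb.N, TMD, BMC}; per side, with any-parameter aggregation to the line
  level.  A category is abnormal when any of its parameters is flagged by
  the range or Wilcoxon criterion.
- **Missing values** exclude an animal from the affected parameter only;
  the Mahalanobis stage needs complete rows and drops incomplete ones with
  a warning.

## Scores, precision, power (`jointphen.scoring`, `.reliability`, `.power`)

- Weighted OARSI score = score + (5 − N)(score/N), rounded to the nearest
  0.5 with ties (x.25/x.75) rounded up — the rounding direction is left
  open by "nearest 0.5" and fixed here.  Compartment summaries report
  per-compartment sums and maxima plus total joint sum and max.
- Synovitis severity is the plain sum of three 0–3 subscores.
- Precision: per-sample SD (n − 1) and 100·SD/mean, RMS-averaged across
  samples.  ICC(A,1) (two-way model, single measure, absolute agreement)
  from the ANOVA mean squares, with the Satterthwaite F-based 95% CI;
  ICC > 0.8 is reported as excellent.
- Power: index (z₁₋α/₂ + z₁₋β)² (7.85 at α = 0.05, 80%);
  N = ⌈2·index·σ²/d²⌉ (4 animals at d = 2σ; the ceiling of 6.498 at 95%
  power is 7, so only the 80% design point is asserted); minimum
  detectable effect d = σ√(2·index/n).  MAD replaces σ for non-normal
  parameters.
- Prioritization (max 21): joint severity (≤ 6), skeletal phenotypes in
  five external resources (≤ 5, one per database), expression in four
  skeletal tissues/cells (≤ 4), disease association (≤ 4: monogenic via
  MGI and via OMIM one point each, GWAS arthritis, GWAS skeletal — the
  composition reaching the stated cap of 4 from three named sources is an
  interpretive decision), and literature bins (≤ 2; PubMed 0/<1, 0.5/1–24,
  1/>25; Scholar 0/<100, 0.5/100–999, 1/>1000, with the boundary gaps at
  exactly 25 and exactly 1000 resolved upward with a warning).  Database
  searches themselves are out of scope; flags and counts are inputs.
- Fisher's exact test is two-sided by the minimum-likelihood convention
  (sum of all tables with fixed margins whose probability does not exceed
  the observed table's), matching the convention of the R environment; a
  one-sided alternative is available through scipy directly.

## Synthetic data (`jointphen.synthetic`)

One user seed drives every generator through named `SeedSequence`
sub-streams, so outputs are bit-reproducible and adding a generator call
never perturbs another's stream.

- **Surfaces** (default 1536² px / 1800 µm field): a smooth textured
  mid-gray 16-bit field (texture amplitude is a free knob — no noise model
  for the real imaging texture is available) carrying dark jagged
  polyline cracks of width length/aspect (aspect ≥ 6 keeps digital
  circularity < 0.5), dark compact debris disks, and 1–3 px bright
  speckles.  Objects are rejection-placed with a 5-px clearance so the
  ground-truth mask has exactly the requested number of crack components.
  Healthy-joint defaults give damage fractions in the low single digits.
- **Radiographs**: uniform plastic and steel patches at known boxes, a
  rectangular bone object of known width and top row with a vertical
  density gradient, optional Gaussian noise.
- **Volumes** (default 160 × 132 × 132 at 2 µm): contrast bath
  (600 mg HA/cm³) over a cartilage slab (120), a solid subchondral plate,
  a trabecular lattice (700) in soft marrow (100), and a low-density
  growth-plate layer.  The plate is as thick as the lattice walls so the
  bone phase has a single nominal thickness.  Two lattice kinds: "grid"
  (crossing walls, fill 1 − (1 − t/s)²; realistic connectivity, but wall
  junctions host larger inscribed spheres so mean Tb.Th genuinely exceeds
  t, and thickness truths are not stated) and "plates" (parallel plates,
  fill t/s, exactly analytic Tb.Th = t, Tb.Sp = s − t, Tb.N = 1/s).
  Defaults use even voxel counts per feature so the ±1-voxel digital
  thickness ambiguity stays within 5%.  The miniature cross-section means
  a 14%-wide VOI is narrower than one lattice period; VOI-local BV/TV is
  therefore compared against the emitted mask, not the global fill.
- **Cohorts**: Gaussian copula over 18 parameters (9 per side) with
  normal or log-normal marginals; mutant effects in SD units applied on
  the latent normal scale, so shifts are well-defined for skewed
  parameters.  Default marginals are plausible healthy values (damage
  area log-normal with sub-percent median; other parameters normal with
  ~10% CV); default correlation is 0.3 within a side and 0.1 across
  sides.  The defaults reproduce the screen's design conditions (100
  reference animals; mutant lines n = 3–10).

What the generators do **not** emulate: image formation physics (SEM
charging, X-ray scatter, beam hardening, contrast diffusion), anatomical
shape variation, segmentation-relevant pathology other than the modelled
lesions, and real between-parameter correlation structure.  Passing tests
therefore demonstrate the correctness of the measurement and screening
arithmetic on data with known truth, not robustness to every artifact of
real scans.

## Problem sizes

The shipped tests run the damage pipeline on 40–50 full-size (1536²)
synthetic surfaces, morphometry on ~160 × 132 × 132 volumes, robust
distance calibration at n = 2000, and the detection-power simulation over
1000 cohorts of 100 + 4 animals — sizes chosen so the whole suite
completes in a few minutes while leaving the statistical tolerances
meaningful.

## Known limitations

- The χ² outlier cutoff applied to robust distances is anticonservative
  per animal for p close to n/5 and for skewed marginals (see above); the
  original screen shares this property.
- The effective-tests threshold of a synthetic cohort depends on its own
  correlation matrix; 0.00568 is specific to the original reference
  cohort's N_eff = 8.8.
- Local thickness is exact only to its radius-bin width (≤ one voxel
  layer); sub-voxel structures are not resolved.
- The JSR pipeline measures projected (2D) damage area; out-of-plane
  damage geometry is invisible by construction.
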