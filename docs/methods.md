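# Methods

This note documents the models, numerical conventions, calibration and
known limitations of `palaeoflight`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Flight-performance model

Steady weight support (`½ ρ_air U² S C_L = m_body g`) gives the scaling
`U ∝ √WL` with wing loading `WL = m_body / S`; the wingbeat-average lift
coefficient and all wingbeat kinematics are held constant, so only
*relative* speed between cohorts is meaningful — the package reports speed
ratios, never absolute speeds.  Available mass-specific power is proxied by
the relative flight-muscle mass `m*_muscle = m_muscle / m_body`, and flight
efficiency by the aspect ratio `AR = b²/S`, since lift-induced drag scales
inversely with AR.

**Planform convention.**  A wing outline is reoriented to its principal
long axis using the polygon's area second-moment tensor (density-free, so
vertex spacing does not bias the axis).  The mirrored-pair convention is
`b = 2 × single-wing length` (body width excluded) and `S = 2 × single-wing
area`; with it, typical cicada-like proportions give forewing AR in the
printed 6–8 range.  `c = S/b`, `AR = b²/S` holds to machine precision by
construction.

**Body model.**  Pro- and mesothorax are ellipsoids of revolution with
circular cross-section of diameter `w_thorax` (volumes `(π/6) l w²`); the
abdomen is a cone tapering from thorax width (`(π/12) l w²`).  Per-group
multiplicative shape factors `k_pt, k_mt, k_ab` (default 1) absorb
group-specific geometry adjustments and make the model swappable.  Masses
assume the density of water (1 g/cm³): `m = 10⁻³ g/mm³ × V`.  Relative
muscle mass reduces to `m* = l_mt / (l_pt + l_mt + l_ab/2)` at equal shape
factors — independent of thorax width, which is why body-width calibration
(for WL) and muscle-fraction calibration decouple cleanly.

**Wing loading area.**  Which wing area enters WL is configurable
(`wl_area = combined_pair | forewing_pair`); the default uses the combined
(forewing ∪ hind wing) pair area, the choice that reproduces the printed
WL magnitudes together with the body calibration below.

## Elliptical Fourier analysis

Outlines are stored counterclockwise (clockwise input is silently reversed
and logged) and resampled to `n_points` (default 300) equally spaced
points by arc length.  Resampling starts at a canonical anchor — the
vertex farthest from the polygon centroid — so the resampled polygon, and
hence every downstream coefficient, is exactly independent of where the
digitized point sequence began.  The EFD coefficients are the closed-form
Kuhl–Giardina segment sums, which are exact for a polygonal contour (no
quadrature error); the suite verifies them against dense numerical
quadrature on a square.

Normalization uses the first harmonic: a phase rotation aligns the
starting point with the first ellipse's major axis, a spatial rotation
aligns that axis with x, and division by the semi-major length removes
size.  The starting-phase angle is only defined modulo π; the residual
180° ambiguity is resolved by a deterministic sign canonicalization of the
higher harmonics (harmonic n flips by (−1)ⁿ⁺¹ between branches; the branch
whose first non-negligible higher-harmonic entry is positive is chosen).
With exact segment integrals plus the canonical anchor, normalized
coefficients agree to ~1e−15 under rotation, scaling and start-point
shifts — comfortably inside the 1e−6 contract.

One parameterization subtlety: under arc-length traversal an *eccentric*
ellipse is not a pure first harmonic (only a circle is), so "all power in
harmonic 1" is asserted for circles and for constructed single-harmonic
series, and Parseval's identity is checked against the exact mean-square
of the piecewise-linear signal.

Harmonic power is `(a² + b² + c² + d²)/2` per harmonic, reported as
cumulative fractions of the total over the computed harmonics (21 are used
when measuring the power captured at 7).  Shape PCA runs on the flattened
normalized coefficients with the three normalization-fixed entries
(a₁, b₁, c₁) dropped by default (configurable), via SVD of the centered
matrix; a rank-zero input yields a degenerate all-zero space rather than
an error.

## Synthetic fossil cohorts

The generator is the package's stand-in for the study's specimen data and
defines its study conditions; its defaults are calibrated once and are not
per-analysis knobs.

**Wing outline family.**  A chordwise half-width profile
`g(u) ∝ uᵖ(1−u)^q` (peak-normalized, u ∈ [0,1] along the long axis) with
exponents `p = ½ + ½τ`, `q = ½ + 2τ` interpolates from an exact ellipse at
triangularity τ = 0 to a base-heavy, straight-tapered subtriangular
planform at τ = 1; the rectangle-fill statistic `area/(L·W)` decreases
strictly monotonically along the sweep (π/4 → ≈0.52).  Leading and
trailing edges share the profile with a fixed 40/60 amplitude split, plus
an optional low-order smooth perturbation (2% amplitude) for boundary
realism.  Vertices use cosine spacing (≥ 64 points; default 200).

**Sub-regions.**  Costal, clavus and extended-costal ("Peco") regions are
cut from the forewing polygon by straight lines tilted 25° toward the
base (anterior cut for costal/Peco, posterior for clavus); the cut offset
is solved by bisection so the region's area fraction equals the drawn
target essentially exactly, making area proportions known by
construction.  The published delineation of the extended costal area is
figure-only, so Peco defaults to 1.8 × the costal fraction and is
configurable.

**Hind wings and the combined silhouette.**  The forewing:hind-wing length
ratio is drawn log-normally and clipped to respect the group rule — early
and dunstaniid taxa ≤ 1.8, late taxa > 1.8.  The default placement for the
combined outline shifts the hind wing 10% of the forewing length tipward
and 0.75 × (forewing trailing half-depth + hind-wing leading half-depth)
posteriorly, giving a realistic coupled-pair overlap; the combined outline
is the shapely polygon union (disjoint placements are returned as a
flagged multi-part union for the caller to handle).

**Distributions and calibration.**  Linear dimensions are log-normal
(positive, right-skewed, as size data are).  Body-segment length ratios
were solved in closed form so the median `m*` is 0.54 (early) and 0.68
(late); forewing slenderness, hind-wing breadth and thorax width were then
solved numerically (fixed-point iteration on 200-taxon cohorts) so the
measured cohort medians reproduce the published values: AR_forewing
6.10/7.0, AR_combined 3.4/4.3, WL 0.39/0.75 g/cm², S*_costal 0.081/0.054,
S*_clavus 0.085/0.049.  The late group draws log-slenderness with slope
0.8 on standardized log length plus residual sd 0.17, chosen so the
log(AR)–log(b) Pearson correlation is ≈ 0.68; the early group has slope 0
(no allometry).  The solved constants live in
`palaeoflight.synthetic.DEFAULT_CALIBRATION`.

Body draws are independent of wing draws within a taxon (beyond the group
membership); real animals correlate body and wing size, so WL spread per
cohort is somewhat wider than a size-correlated model would give.  The
AR_combined cohort median consequently carries the widest sampling noise
of the six traits (its synthetic IQR is as wide as the printed 2.8–4.0 /
4.0–5.5 ranges), so the early↔late percent difference recomputed from a
single 200-taxon cohort scatters several points around the analytic 26%.

**Character matrices.**  Each group has an archetype state vector;
archetypes differ per character with probability `divergence` (0 makes all
taxa exchangeable, so group tests are exact nulls — the default
`within_noise` is therefore a scalar, 0.15).  Each taxon resamples
characters at its group's noise rate; the pipeline passes a per-group dict
(early 0.25, late 0.10) so the early group occupies more morphospace, the
configured analogue of the published disparity contrast.  Missingness is
completely at random (fossil missingness is structured in reality; no
information here to model it), with a guard keeping ≥ 1 observed state per
taxon.

**Stratigraphic labels** are drawn from the fixed epoch vocabulary with
weights patterned on the published per-epoch species tallies, to exercise
the diversity-tally stage.

## Disparity and morphospace

MORD sums per-character differences over mutually observed characters and
rescales by the maximum possible difference over those characters
(unordered: 0/1 with max 1; ordered: |Δstate| with max = the character's
observed range), so it is bounded in [0,1]; pairs with no comparable
character are masked, and masked entries are imputed with the matrix-wide
mean distance before ordination (logged; taxon deletion is the documented
alternative).  GED sums squared differences with the pair's mean observed
difference imputed for incomparable cells, then takes the square root.

PCoA double-centers the squared distances and eigen-decomposes; axes with
eigenvalues below 1e−9 × the spectral radius are dropped.  The Cailliez
additive constant (largest eigenvalue of the 2n × 2n companion matrix) is
applied by default when negative eigenvalues occur; in `"none"` mode
negative axes are simply excluded from disparity.  Disparity uses all
retained positive axes by default (axis count configurable): SOV = Σ
sample variances (n−1), SOR = Σ ranges, MDC = median Euclidean distance to
the centroid.  Bootstrap CIs are plain percentile intervals (lower ≤ upper
always).  Group comparison applies Welch's t to the two groups' bootstrap
distributions, mirroring common practice in the disparity literature; this
is anti-conservative (bootstrap replicates are not independent draws from
the sampling distribution) and the resulting p-values should be read as
descriptive.  PERMANOVA uses the Anderson pseudo-F on squared distances
with `p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)`, 999 permutations by
default, seeded.

Which distance fed the published PERMANOVA is not stated; both MORD and
GED are supported (MORD default).  Polymorphic NEXUS codings like "(01)"
are collapsed to missing on read (logged), as their original treatment is
unknown.

## Comparative statistics

Welch's t with Welch–Satterthwaite df; two zero-variance samples with
equal means return t = 0, p = 1, with different means an infinite-t flag.
Pearson p-values use the t transform on n−2 df.  The ANCOVA fits
`log AR ~ log b * group` by OLS and reports the type-II interaction F; in
the two-group case this equals the squared standardized slope contrast
(verified to 1e−8).  Natural logs throughout (base changes only shift
intercepts).  Normality is checked by Shapiro–Wilk and variance
homogeneity by Bartlett's test — the naming in the source literature
conflates Levene with `bartlett.test`; Bartlett is what runs here.
Medians use the even-n midpoint convention; percent differences are
reported rounded to the nearest integer (configurable).

## Problem sizes and determinism

Default study conditions use 200 taxa per group for calibration-recovery
measurements, 50 outlines for the harmonic-power summary, ≥ 200 replicates
for null-rate simulations, 500–1000 bootstrap draws and 999 permutations —
sizes at which the reported medians are stable to well inside their
tolerance bands while the whole suite runs in about a minute.  Every
random stage draws from a `numpy` `SeedSequence` spawned from a single
seed, so any report is byte-reproducible from its recorded (config digest,
seed) provenance; cohorts serialized to disk and re-read measure
identically to in-memory cohorts.

## Known limitations

- Wingbeat kinematics, lift-coefficient variation and unsteady
  aerodynamics are out of scope; speed and power statements are relative
  scalings only.
- The geometric body model's exact published primitives (and the
  "slightly adjusted" group modifications) are figure-only; the shape
  factors default to 1 and are deliberately swappable.
- The published "19% higher" relative muscle mass is arithmetically
  inconsistent with the printed medians 0.54 → 0.68 (≈ 26%); the package
  computes percent differences from medians and does not target that
  figure.
- Synthetic cohorts model no taphonomic deformation, no phylogenetic
  correlation among traits, and no body–wing size correlation; passing
  calibration tests shows the pipeline recovers the cohort statistics it
  was pointed at, not that real palaeontinid data would behave this way.
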