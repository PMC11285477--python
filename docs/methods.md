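# Methods

This note documents the models, conventions and numerical choices behind the
package, in the spirit of a software methods section: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

All heights and lateral spacings are in µm; readers convert on load (SDF
scales are metres on disk). Row index is y, column index is x, origin at the
top-left; angles are measured counter-clockwise from +x and reported modulo
180°. Masked (non-measured) points are excluded from every area-normalised
statistic (evaluation area = valid-point count × dx·dy) and are never
interpolated, with one exception: feature segmentation and the FFT-based
spatial parameters need a gap-free grid, so masked points are filled by
nearest neighbour and the result flagged `filled`. Because the fill only
copies measured values, the stored height under a mask can never influence a
parameter (this is tested by injecting masked outliers).

## S-F surface

The F-operator is a least-squares 2-D polynomial of total degree 0–3
(default 2) fitted on normalised coordinates to the valid points; the fitted
form is subtracted everywhere and the residual centred to zero mean. No
S-filter (low-pass) is applied beyond the instrument's own resolution: the
package targets already-resolved confocal height maps, and a degree-2 form
removal is the common DMTA template. The operation is idempotent and the
output is invariant to adding any polynomial of degree ≤ form_degree to the
input (both are tested). Instrument-software templates vary in unpublished
details (form degree, filter nesting); results on real scans depend on
matching the original template, which is why the degree is exposed in
`PreprocessSettings`.

## Parameter battery

Height parameters are plain moments over valid points; a surface with
Sq = 0 reports zero skewness/kurtosis with a `degenerate_surface` flag
rather than NaN. The bearing (Abbott–Firestone) curve maps material ratio
r ∈ [0, 100]% to height by linear interpolation between the sorted valid
heights (highest point at r = 0, lowest at r = 100); the functional volumes
are truncated means against the cutting plane c(r):
Vm(r) = ⟨max(z − c(r), 0)⟩, Vv(r) = ⟨max(c(r) − z, 0)⟩, with the
peak/core/valley split at p = 10% and q = 80%, Sxp = c(50%) − c(97.5%), and
Smr evaluated 1 µm below the highest peak (configurable; the metrology
default when no reference height is given). Sxp's (p, q) orientation follows
the reported convention even though some instrument software defaults to
(2.5%, 50%); both are reachable through `ParamSettings`.

Spatial parameters use the biased FFT autocorrelation (DC removed,
normalised to 1 at zero lag). The decay radius where the ACF first crosses
s = 0.2 is found on 360 azimuths at 1° steps with bilinear interpolation and
half-pixel radial stepping; Sal is the minimum radius, Str the min/max
ratio. When the ACF never crosses s along some azimuth (perfectly 1-D
textures), the decay saturates at the half-field radius and an
`acf_saturated` flag is set. Std is computed from the angular energy of the
Hann-windowed power spectrum (DC and the innermost two frequency rings
excluded to suppress leakage), binned at 1°; the reported direction is the
lay — dominant spectral azimuth + 90° (mod 180°) — so striations running
along y give Std = 90°. Hybrid parameters use central differences
(one-sided at borders).

## Feature characterization

Dales are the catchment basins of the surface's regional minima under
8-connectivity (pixel flooding by `skimage.segmentation.watershed` with
labelled-minima markers); hills are the same computation on the inverted
surface. Wolf pruning removes features whose prominence — the height
difference to the saddle connecting them to a deeper (higher) feature — is
below 5% of Sz, recomputed per scan. Pruning is implemented as persistence
thresholding on the saddle merge tree: region-adjacency saddles (minimum
over the shared boundary of max(z₁, z₂)) are processed ascending through a
union-find with the elder rule (the deeper extremum survives; ties broken by
row-major position), each absorbed feature recording its persistence and its
absorber. This yields the same surviving set as iteratively merging the
least-prominent feature first, and is checked against an independent
brute-force sublevel-set flood-fill oracle on exhaustively enumerated tiny
grids. Features touching the map border count for the peak density Spd but
are excluded from the "closed" means Sda/Sha/Sdv/Shv; a closed feature's
volume is integrated up to its lowest rim saddle. Spc is the arithmetic mean
over significant peaks of −½∇²z by the 5-point Laplacian. With fewer than
five significant peaks or pits, S5p/S5v average what is available and set a
`feature_shortfall` flag.

## Robust statistics

"Trimming to 15%" is interpreted as symmetric per-tail trimming inside the
Yuen/Welch machinery — trimmed means with winsorized variances and
Welch-type degrees of freedom — not as discarding rows from the dataset;
Cliff's method, being rank-based, uses the untrimmed data. With γ = 0 the
omnibus test reduces exactly to Welch's heteroscedastic test (verified
against an independent implementation to 1e-9). The pairwise test uses
Yuen-type statistics with pair-specific Welch df and family-wise p-values
from the studentized maximum modulus distribution with C = number of pairs,
evaluated by fixed-tolerance quadrature (1e-10); for C = 1 it coincides with
the two-sided t distribution. Cliff's variance estimate combines row-, 
column- and cell-level dispersion of the dominance matrix; the CI on delta
is the standard asymmetric back-transform. Monte-Carlo calibration (10 000
replicates, n = 40 + 40) under heteroscedastic lognormal nulls — groups
centred at the population trimmed mean for Welch–Yuen; equal log-median,
unequal log-scale for Cliff — holds the empirical type-I error within
[0.04, 0.06] at nominal 0.05. Note that scale-shifted skewed groups are
*not* a null for Cliff's hypothesis (P(X>Y) ≠ 0.5 there), so each test is
calibrated under the null of its own hypothesis.

Scans (4 per facet) enter the comparisons as replicate rows, not averaged
per specimen. This reproduces the large degrees of freedom typical of DMTA
reports but is pseudoreplication with respect to specimens; users who want
specimen-level inference should aggregate before calling
`compare_parameters`. No multiple-testing correction is applied by default
(per-parameter reporting); Holm's step-down is available via
`StatsConfig(adjust="holm")`.

## Synthetic facet models

The generator emulates the two canonical wear regimes. The background is a
stationary Gaussian random surface with squared-exponential correlation
(spectral synthesis by periodic Gaussian smoothing of white noise, rescaled
to the target SD). Striations are Poisson-count half-cylindrical grooves of
lognormal depth at a set orientation with small angular jitter; craters are
Poisson-count Gaussian-profile pits with lognormal radius and depth.
Defaults (160×160 µm field):

- attrition (shear-cutting facets): σ_base = 0.04 µm, L = 2 µm, 80 grooves
  at 90° (width 1.5 µm, median depth 0.25 µm), 20 craters (radius 2.5 µm,
  median depth 0.5 µm) — an oriented, lightly pitted facet whose dale
  component lets volume parameters carry population-level signal;
- crushing (puncture-crushing facets): σ_base = 0.08 µm, L = 3 µm,
  40 craters (radius 3 µm, median depth 1.2 µm) plus 30 grooves at 30°
  (width 2.5 µm, median depth 0.5 µm) as the dominant oriented component.

Study generation is hierarchical: population effect multipliers
(multiplicative on depths/rates, keeping scales positive) → lognormal
per-specimen random effects (σ = 0.15 on the log scale) → independent scan
noise, four scans per facet, all seeded through `numpy.random.SeedSequence`
spawning so every artifact is a pure function of design + master seed. The
default scan geometry is 512×512 over 160×160 µm; validation suites and the
acceptance script run at 256×256 (dx = 0.625 µm), a grid on which all
parameters are well resolved relative to the feature scales above.

What the generator does **not** emulate: enamel prism microstructure,
instrument noise anisotropy, measurement dropouts correlated with slope,
facet curvature beyond an optional quadratic term, or physically based
contact mechanics. Passing tests therefore demonstrate the correctness and
sensitivity of the measurement/statistics chain under controlled texture
structure — not that any particular real-world contrast will be detected.

## Known limitations

- The watershed/pruning agreement oracle is exhaustive on 3×3 grids but
  sampled (4000 seeded draws) on 4×4 grids: the full 3^16 enumeration is
  computationally out of scope for a test suite.
- Sal/Str depend mildly on the 1° azimuth and half-pixel radial sampling;
  Std is quantised to 1° bins.
- Real instrument templates (µsoft/MountainsMap) are proprietary; parameter
  values on real scans can differ from other software where the standard
  leaves choices open (Smr reference, Sxp orientation, border features).
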