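# Methods

`cartafm` implements the quantitative core of an AFM-based assessment of
articular-cartilage wear: surface-roughness metrology on height maps,
depth-resolved Young's modulus from force-indentation curves, a power-law
model of specimen drying, and a synthetic-data layer that makes the whole
chain testable without instrument data.

## Specimen dehydration

Excised cartilage dries between harvest and measurement; its mass follows

    m(t) = m0 (1 + t)^b,    t in hours,

with the default exponent `b = -14/99 = -0.141414...`. The repeating
decimal admits two readings (`-0.1414...` vs `-0.1444...`); the package
adopts the former because it places a 30 % mass loss at t = 12 h, the point
at which measurements stabilise, whereas the latter gives 31 %. The
exponent is an argument everywhere, so the alternative reading can be used.
Fitting is linear least squares on `log m = log m0 + b log(1+t)` —
deterministic, exact on noiseless model data, and adequate for the ~1 %
multiplicative mass noise of a laboratory balance. The residual sum of
squares is reported in mass space so it is comparable to measurement noise.
The model describes total specimen mass; "liquid lost" is interpreted as
total-mass fraction, which is how the 30 %/12 h anchor is reproduced.

## Roughness metrology

Height maps are plane-levelled (least-squares first-order plane only; the
analysis targets scan areas selected to be free of waviness, and
higher-order detrending would bias Ra). Profiles are taken row-wise,
following the AFM fast-scan raster convention. On a profile with mean
line equal to the post-levelling profile mean:

* `Ra` — mean absolute deviation from the mean line;
* `Rp` — maximum height above the mean line;
* `S`  — mean spacing between consecutive local peaks, where a local peak
  is a sample strictly greater than both neighbours and runs of equal
  height collapse to their first sample. `S` is undefined (an error) with
  fewer than two peaks. No height-discrimination band is applied by
  default; peak definitions with such bands exist, but the synthetic
  surfaces are smooth at the pixel scale and real use can pre-filter.
* `Sa` — the areal analogue of Ra over the full grid.

Lacunae (chondrocyte cavities, seen as elliptical depressions) are detected
as connected pixel regions deeper than a threshold below the median height;
the median is robust to the depressions themselves. Each region is reported
with centroid, area and maximum depth, and the detected count is
non-increasing in the threshold.

Wear staging partitions the worn Ra range [24.6, 61.2] nm (measured at the
9x9 um^2 scan area) into three equal subranges of 12.2 nm: heavy
[24.6, 36.8], medium (36.8, 49.0], small (49.0, 61.2]; Ra above 61.2 nm is
healthy and Ra below 24.6 nm is out of range. Boundary values fall to the
more-worn stage so ties resolve deterministically. The interior boundaries
36.8 and 49.0 nm are derived from the tripartition, not stored.

Summaries report mean, SD (n-1 denominator, 0 for a single value), min and
max per parameter per scan area, and the total record count
(points x specimens x areas). Percent change of a worn extreme against the
healthy mean is `100 (healthy - worn)/healthy`, rounded to the nearest
integer for reporting.

## Hertz indentation analysis

A force curve pairs vertical stage position `Zpos` with cantilever
deflection `Zdefl` (both nm). The tip penetration is `h = Zpos - Zdefl`,
and for a spherical tip of radius R on an elastic half-space the pointwise
modulus is

    E(h) = 3 (1 - V^2) k Zdefl / (4 sqrt(R) h^{3/2}),

equivalently the Hertz force law `F = (4/3) [E/(1-V^2)] sqrt(R) h^{3/2}`
with `F = k Zdefl`. Lengths are converted to metres internally so E is
computed in Pa and returned in MPa; an independent all-SI evaluation agrees
to 1e-9 relative across the probe-constant range. Defaults are the
cartilage probe constants V = 0.5, k = 0.08 N/m, R = 30 nm. Only the
approach (loading) segment is analysed; adhesion and retraction are out of
scope, as are finite-thickness corrections.

Contact detection estimates the baseline mean and SD from the first 20 % of
samples and takes the first index whose deflection exceeds
`mean + 3 SD` for three consecutive samples. This crossing necessarily
overshoots the mechanical touch point (deflection must already exceed the
noise band there), so profile extraction uses the sample immediately before
the crossing as the contact reference for re-zeroing `Zpos`, and the
baseline mean (less noisy than any single sample) for re-zeroing `Zdefl`.
With noiseless synthetic curves this reference coincides exactly with the
true contact sample, giving machine-precision recovery of the prescribed
E(h); with 0.1 nm deflection noise the detected index is within +-2 samples
of ground truth in >= 95 % of trials at the default sampling.

E is evaluated pointwise for depths at or above `h_min` (default 10 nm,
configurable), guarding the `h^{-3/2}` divergence near contact. Small
negative depths within the baseline noise band near contact are clipped to
zero; depths clearly below zero (beyond six baseline SDs) raise, signalling
a mis-detected contact. Repeat measurements are averaged pointwise after
linear resampling onto the overlap of their depth ranges. A profile is
summarised by its surface modulus (value at the shallowest depth) and its
maximum (value and depth), the two quantities that separate healthy from
worn tissue: healthy E(h) declines monotonically so surface and maximum
coincide, while worn surfaces rise to an interior maximum.

## Synthetic data

The generators define the study conditions and carry their own ground
truth; they are first-class, tested code.

**Surfaces.** White Gaussian noise is smoothed with a Gaussian kernel of
sigma = `correlation_length / (sqrt(2) pixel_size)` pixels, giving the
field a Gaussian autocorrelation with 1/e half-width equal to the
correlation length (default 250 nm — a few collagen-fibre diameters). The
smoothed field is rescaled so the grand mean of per-row profile Ra equals
the target exactly (the statistic is linear in field amplitude), then
lacunae are subtracted and a tilt plane added. Lacunae are raised-cosine
elliptical bowls — full depth at the centre, zero at the ellipse boundary,
continuously differentiable — so levelling and peak detection stay
well-posed; a lacuna whose ellipse extends beyond the grid is rejected.
Default cohort targets follow the healthy summary table per scan area
(Ra 28/86/96 nm at 3x3/9x9/18x18 um^2) with worn targets inside the worn
range (10/30/65 nm). The generator emulates amplitude and correlation
structure only: no tip convolution, drift, scan-line noise, or
quantitative collagen-fibre texture — so passing tests validate the
metrology chain, not robustness to instrument artefacts.

**Force curves.** The prescribed E(h) (constant or depth-varying, in MPa)
is forward-inverted through the Hertz relation on a uniform depth grid over
[0, h_max]; `Zpos = h + Zdefl`; a flat baseline is prepended and the true
contact index recorded. Gaussian noise (default 0.1 nm, typical of a soft
cantilever in liquid-free operation) is added to `Zdefl` only — `Zpos` is
treated as exactly commanded, matching AFM practice. Default sampling is
100 contact samples over 300 nm depth (about 3 nm per sample) with 30
baseline samples.

**Drying series.** The power law with multiplicative Gaussian noise on the
mass. All generators take explicit integer seeds; there is no hidden
global state.

## Study pipeline

The roughness study generates one surface per specimen per scan area,
measures five non-overlapping sub-windows per surface — chosen by seeded
sampling from a 3x3 slot grid, since the measurement-point placement is a
protocol detail, not data — and produces exactly
`points x specimens x areas` records (375 for 25 specimens, 1125 for 75).
Each sub-window is levelled independently; Ra and Rp are means of per-row
values and S the mean over rows with at least two peaks. Summaries,
percent changes against the healthy group, and per-specimen stages (from
mean Ra at the 9x9 um^2 area) follow. The percent-change table carries both
the change of the worn mean and of the worn minimum against the healthy
mean; the published comparison uses the extreme, the cohort-level check
uses the mean.

The indentation study uses built-in ground-truth E(h) models per wear stage
and layer (surface layer 1, cross-section layers 2 and 3): healthy layers
decline 1.7 -> 0.5 MPa; worn surface layers rise from 1.14/1.02/0.82 MPa to
a maximum of about 1.3/1.2/1.2 MPa near 120 nm depth before declining;
worn cross-sections decline monotonically (1.2 -> 0.65, 1.0 -> 0.6,
0.8 -> 0.6 MPa). Three noisy repeats per stage/layer are averaged and
summarised. Reports are written with fixed column order and 4-significant-
digit floats, so reruns with identical config and seed are byte-identical.

Default test and demo problem sizes (96-128 px maps, cohorts of a few to
100 specimens, 130-sample curves) were chosen so the full suite runs in
seconds while every statistic is estimated from hundreds of records; all
sizes are configuration, and the full 25 + 75 cohort runs in a few seconds.

## Known limitations

* The Hertz half-space assumption ignores finite specimen thickness and
  adhesion; no Dimitriadis/JKR/DMT corrections are provided.
* Roughness parameters are the profile set (Ra, Rp, S) plus areal Sa; the
  full ISO 25178 areal suite and spectral waviness separation are out of
  scope.
* The wear scale mixes conventions in its sources: the healthy mean
  (86 nm) refers to the 9x9 um^2 area while "wear onset" near 73 nm appears
  to reference 18x18 um^2; staging here is defined strictly at 9x9.
* Synthetic surfaces are Gaussian and isotropic; real cartilage has
  fibrous anisotropy the generator does not emulate.
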