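# Methods

This note documents the models, numerical choices and assumptions behind
`panomap`, and what the synthetic validation does and does not establish.

## Mapping surface and sensor layout

The ventricular surface is modeled as a tri-axial ellipsoid
(x/a)² + (y/b)² + (z/c)² = 1 with z up toward the heart base and the apex at
(0, 0, −c); a horizontal plane removes the top `truncation_fraction` of the
vertical extent 2c (0.25 for the reference cup, leaving z ≤ c/2). All
lengths are millimeters, times milliseconds, rates Hz, velocities mm/s.

Meshing places vertex rings along lines of constant latitude at equal
meridian-arc increments, sizes each ring by its perimeter, and stitches
adjacent rings with a two-pointer zipper; the apex (and, for a closed
surface, the top pole) is a triangle fan. The result is watertight below the
cut: Euler characteristic 2 closed, 1 truncated. Median edge length tracks
the requested target within 25%.

Geodesics are computed as Dijkstra shortest paths over mesh edges followed
by elastic (midpoint) relaxation of the polyline constrained to the surface;
pure edge walks overestimate lengths by up to ~8% on triangulated surfaces,
relaxation brings the 90°-arc error on a unit sphere below 1%. Site-to-site
distances use the same relaxation seeded from the projected chord, which
converges quickly for the sub-centimeter separations that matter here.

Layout packing: sites are initialized by an area-weighted golden-angle
spiral, equalized by Lloyd iteration against a dense (25 000-point) surface
sample, then polished by local repulsion until the minimum pairwise distance
stops improving (relative change < 1e-4) or the iteration budget (500) is
spent. Counts are inputs, not emergent: the reference cup carries exactly
64 electrodes + 294 optical fibers. A feasibility check rejects requests
whose hexagonal cell area (√3/2 · pitch²) exceeds the available surface.
At the reference density the packing equilibrates at a mean nearest-neighbor
spacing of ≈ 0.66 mm for a 0.7 mm nominal pitch (the surface holds 358
sites at ~94% of the nominal hexagonal spacing), with coefficient of
variation ≈ 0.06. Electrodes are selected by farthest-point sampling
(deterministic start at the lowest site) so they cover the cup evenly; each
receives up to six optical petals within 1.9× the realized mean spacing.

Projections: Mercator maps a surface point to (longitude = atan2(y, x) in
degrees, y = ln|tan(π/4 + φ/2)| with φ = asin(z/c)); the vertical axis has
no longitude and is rejected. The central (azimuthal) projection uses the
geodesic arc distance from the apex as radius and longitude as angle.

## Optical action potentials

Traces are the mean (or normalized-Gaussian-weighted) central 3×3 pixels of
each fiber's 5×5 block. Saturation is detected at pixel level before
averaging and propagates as a per-sample mask; any AP containing a clipped
sample is excluded with reason.

Drift is removed by a polynomial (default order 3) fitted to samples outside
detected AP intervals; the fit is evaluated only inside the baseline's time
span (clamped at its ends) because extrapolating a cubic across a masked AP
that extends to the record edge diverges. The mean baseline level is
restored so ΔF/F stays computable.

AP detection thresholds the Savitzky–Golay derivative (default 2nd order,
window ≈ 1 ms of samples, minimum 5) at 5× its robust noise SD (1.4826·MAD).
Supra-threshold regions closer than 10 ms are fragments of one upstroke
(noise dips, feet, multiphasic rises) and merge; within the 30 ms refractory
window a region with a comparable derivative peak (≥ 50% of its neighbor's)
is a genuinely close second AP — kept separate and flagged, never silently
merged. Regions touching the filter's edge half-windows are discarded as
edge artifacts. On a noiseless trace the threshold degenerates to "any
appreciable derivative".

Metrics per AP: the segment is pre-padded by max(SG window, 10 ms) so slow
upstrokes that cross the detection threshold mid-rise keep their foot;
amplitude and level crossings are read off an SG-smoothed copy (a single
noise excursion must not set the APA; at SNR 20 the raw maximum of a
~1 500-sample plateau would inflate APA by ~15%), while the SNR denominator
stays the unfiltered 50 ms rest window. ΔF/F = 100·(peak − baseline)/baseline;
the AP is normalized to APA = 100% before differentiation so dV/dt_max is in
%APA/ms; oLAT₅₀ is the linearly interpolated first 50% crossing (earliest on
ties, flagged if multiple); APD(x) runs from oLAT₅₀ to the first recovery
below (100 − x)% — first-crossing semantics make APD monotone in x by
construction. The APD onset reference (50% upstroke crossing) is a package
convention; an activation-time reference would shift all APDs by a constant.

Upstroke shapes: qualifying derivative peaks are those ≥ 15% of the maximum
with half that prominence. Two peaks ≥ 1 ms apart with an intervening trough
≤ 60% of the first peak → two-phase (shape 3); a 5–20% APA foot lasting ≥ 2×
the 20–80% rise time before a single peak → foot type (shape 1); a single
peak otherwise → uniform (shape 2); fewer than 3 samples between 10 and 90%
APA → unclassified (coarse sampling, e.g. 250 Hz, cannot resolve shape).

## Electrograms

The beat window defaults to ±40 ms around the steepest negative SG slope of
the record (stimulus-locked windows when stimulus times are known). The
downstroke is the maximal peak-to-trough negative deflection: amplitude =
preceding local maximum − trough, duration their separation, eLAT_SG the SG
derivative minimum inside it (earliest on ties). A deflection must clear the
expected peak-to-trough range of pure noise — noise SD (robust, from first
differences) times max(4, 3·√(2 ln n)) for an n-sample window — because a
fixed 4·SD criterion never rejects an 800-sample noise window whose expected
range is ≈ 7·SD. Stimulation artifacts are blanked by linear interpolation
over ±window around each stimulus; a downstroke overlapping a blanked span
is excluded ("artifact overlap"). Channel-level exclusion replaces visual
inspection with a quantitative rule: ≥ half the beats unusable for the same
reason.

## Conduction velocity and anisotropy

LAT-vs-distance is fitted by ordinary least squares along a trajectory; the
slope has units ms/mm, so θ is reported as the reciprocal slope in mm/s
(θ in mm/ms is numerically θ in m/s). Fitting LAT against distance (rather
than distance against LAT) treats distance as the error-free regressor,
which matches how the trajectories are constructed. Trajectory LATs come
from inverse-geodesic-distance-squared interpolation over the 4 nearest
mapped sites (exact at sites; queries farther than 2× pitch from any site
are rejected). The directional scan marches geodesic rays (project-and-
transport, step = half the LAT sampling spacing) in 36 equally spaced
tangent directions over 3 mm (rays stop at the truncation rim), keeps fits
with r² ≥ 0.9, takes the fastest, and measures the perpendicular along the
90°-rotated ray. Retrograde or flat fits are errors, not zeros.

## Fluorometry

Budget components live on one common absolute intensity scale; the
underestimation factor is total/reporter of that budget and corrected ΔF/F
is measured × factor. With components 47.9/44.0/8.1 the factor is 2.09; a
dim reporter at 11.8 on the same scale gives 5.42. Interpreting the dim
reporter's 11.8 on the bright heart's scale (rather than per-heart
percentages) is the only reading consistent with both printed factors.

## Virtual heart

Wavefront: first-arrival times for an elliptic group-velocity profile
v(φ) = θ_L·θ_T / √(θ_T² cos²φ + θ_L² sin²φ), φ the angle to a fiber
direction field at constant angle to the circumferential tangent. Solved as
Dijkstra with direction-dependent edge costs on the mesh graph augmented
with 2-hop chords (cutting the graph-metric anisotropy error from ~7% to
~1–2%), seeded by an exact tangent-plane near field (r/v(φ) within ~1 mm of
the origin, attached via a virtual source) because discretization error is
worst where few edges average out. Sites inside the near field get direct
times; others take the earliest anisotropic extension from their 6 nearest
vertices. The fiber field degenerates at the apex pole (the circumferential
direction is undefined there), so simulated pacing sites should sit on the
free wall — as they do in the bundled examples and acceptance run. This is
an eikonal model: no ionic currents, no wavefront curvature effects, no
repolarization gradients.

Optical traces: membrane template = logistic upstroke (10–90% rise time,
default 1 ms) × logistic repolarization placed so APD70 (default 42 ms, the
fast-dye regime; repolarization scale 8 ms) is honored; filtered by an
asymmetric first-order kinetic model (τ_on rising, τ_off falling — exact
discrete recursion). The bundled indicator presets are package assumptions,
not measurements: fast dye 0.05/0.05 ms, slow bright reporter
3.5/10 ms with 7.12% sensitivity, fast dim reporter 1.0/1.5 ms with 3.47%
sensitivity. Baseline = budget total; APA = sensitivity × reporter fraction
× baseline, so the measured ΔF/F automatically shows the background
dilution. Gaussian noise per channel from seeds spawned in fixed order
(`SeedSequence(seed)`) makes datasets bit-reproducible.

Electrograms are constructed so the estimator is unbiased by design
(−gain × kinetics-free template + a small far-field R lobe: steepest
negative slope exactly at the true LAT); this isolates indicator-kinetic
bias — the quantity of interest — from electrode modeling. Stimulation
artifacts are biphasic square pulses confined to ±width around each
stimulus. Frame rendering paints each trace into its 5×5 block with a
Gaussian radial profile (σ = 0.9 px; the central 3×3 carries ≈ 85% of the
intensity), so extract∘render is a constant gain.

## What the synthetic validation shows — and does not

Passing tests establish that the estimators are unbiased and tight under
their own forward model: LAT recovery to < 0.1 ms at 10 kHz/SNR 15,
θ and anisotropy recovery to a few percent (median over 20 configurations:
≤ 7% and ≤ 10% respectively, measured at ~2% and ~3.5%), the τ·ln 2 kinetic
delay, and sub-millisecond opto-electrical concordance with fast indicators.
Real recordings add what the generator omits: motion residue, spatially
correlated noise, photobleaching beyond polynomial drift, septal far-field
contributions (the simulator builds two-phase upstrokes as explicit
fixtures instead), electrode polarization and AC-coupling transients, and
wavefront collisions from multi-site breakthroughs. Quantities measured on
real hearts therefore inherit assumptions the synthetic tests cannot check.

## Problem sizes and defaults

The bundled analyses use a 0.35 mm mesh (~1 650 vertices) for the reference
cup, 300 ms records at 10 kHz, and one beat per dataset; these sizes keep
the full suite and the acceptance script to desk scale while leaving the
estimators' errors (above) far from their tolerances. All tunables —
SG window/order, detection threshold and refractory, drift order, APD
levels, minimum petals, scan granularity and trajectory length — are exposed
through `AnalysisConfig`, which rejects unknown keys.

## Known limitations

Counts are imposed, not emergent, so the packing cannot discover that a
given pitch "naturally" yields 358 sites. The mean realized spacing sits a
few percent below the nominal pitch whenever the requested density is near
the hexagonal limit. Geodesic rays and the eikonal graph both discretize the
same surface, so conduction estimates are not fully independent of the
simulator's mesh (the CV fit, interpolation and ray marching are, however,
independent of the Dijkstra metric). Shape classification thresholds are
heuristics tuned on constructed fixtures; borderline two-phase upstrokes
under heavy noise fall back to "unclassified" rather than guessing.
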