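# Methods

## Scope and model

`spindrift` analyses a coastal tracer-release experiment in which a
fluorescent dye (rhodamine WT, RWT) stands in for water pollution. The
measurement chain has four stages: fluorometric quantitation of the
tracer in aerosol collection liquids, conversion to air concentration,
blank-based detection, and wind/tide attribution of each air sample to
a sea-surface source window. A synthetic campaign generator provides
ground-truthed inputs for every stage.

All geometry is local Cartesian metres (x east, y north). Wind
direction is meteorological throughout: the direction the wind blows
FROM, degrees clockwise from north. This convention is enforced in one
place (`spindrift.core`) because a silent TO/FROM mix-up is the most
damaging failure mode in source attribution.

## EEM quantitation

An excitation–emission matrix (EEM) is fluorescence intensity on a grid
of excitation 425–625 nm (5 nm steps) by emission 248–~824 nm (4.5 nm
steps). Processing is a strict state machine, raw →
background-corrected → Raman Units:

1. **Background correction** subtracts the mean intensity of a
   configurable low-signal rectangle from the whole spectrum. The
   default rectangle (excitation 600–625 nm, emission 248–300 nm) is the
   corner farthest from both the RWT peak and the water-Raman ridge. The
   operation is idempotent for a fixed rectangle.
2. **Raman normalisation** divides by the trapezoid-integrated
   water-Raman peak of a pure-water reference scan, giving Raman Units
   (RU) so sessions with different lamp/detector gain are comparable.
   The conventional band (excitation 350 nm, emission 380–420 nm) lies
   *off* this instrument's excitation grid, so the band is fully
   configurable; the synthetic instrument normalises at the lowest
   on-grid line, excitation 425 nm, over ±17 nm around the Raman-shifted
   emission (~497 nm at the standard 3400 cm⁻¹ Stokes shift). Because
   sample and standards share the normalisation constant, quantified
   concentrations are invariant to the choice (tested).
3. **Calibration** fits, per pixel, the least-squares response slope
   (RU/ppb) across ≥3 standards of known concentration. Constant
   features (background residue, Raman ridge, ambient fluorophores that
   do not scale with the tracer) cancel out of this slope map, which
   therefore is the pure tracer spectral shape; stored unit-normalised
   as the reference pattern. The three highest-slope pixels inside a
   window bracketing the RWT maximum (558/582 nm; the window prevents
   noise spikes far from the peak being selected) become the
   quantitation peaks — on this grid the top peak is excitation 560 nm,
   emission 581 nm. The calibration line is ordinary least squares of
   mean-of-three-peaks intensity vs concentration. The mean is used as
   the combiner because it is the simplest symmetric statistic; a joint
   fit of the three peaks would differ only at second order in noise.
4. **Quantitation** inverts the line at the mean-of-three-peaks
   intensity and floors at zero (a concentration cannot be negative;
   blank-level noise otherwise produces small negatives).
5. **Pattern detection** declares the tracer present when (a) the
   centred Pearson correlation between the EEM and the reference
   pattern over a signal region around the peak is ≥ 0.9 and (b) every
   quantitation peak is the maximum of its 5×5-pixel neighbourhood,
   excluding the other quantitation peaks (the three peaks are adjacent
   pixels on one smooth ridge, so each other's neighbourhoods overlap).
   Both criteria are invariant to positive rescaling of the EEM. The
   0.9 threshold is a configuration knob, not a derived constant; it is
   reported alongside outputs. The signal region default (excitation
   533–608 nm, emission 537–627 nm) deliberately excludes the
   water-Raman ridge, which crosses longer emission wavelengths only
   below ~528 nm excitation.

## Air concentration and detection

The sampler draws 450 l/min (27 m³/h) and concentrates the collected
air into a 10 ml liquid. With 1 ppb = 1000 pg/ml,

    mass_pg  = [RWT]_liquid × 1000 × V_liquid(ml)
    [dye]_air = mass_pg / V_air(m³).

From ≥2 field blanks, α = mean, β = sample standard deviation (n−1
denominator), and

    LoD = α + 3.29 β.

3.29 is twice the one-sided z at 95%, the standard blank-based
detection-limit multiplier controlling false positives and false
negatives at 5% each. Renderings of this formula occasionally show a
minus sign; the additive form is the convention, and it is the form
under which the bundled field campaign's printed LoD (32.8 pg/m³)
follows from its four blanks (2.0, 7.3, 18.9, 10.0 pg/m³ → α = 9.55,
β = 7.0638). The LoD is always computed from the unrounded chain;
rounding the blank statistics first (9.5, 7.1) would not reproduce the
reported value. Above-LoD uses a strict inequality; boundary ties are
visible in the output flags.

A *detection* is the conjunction: spectral pattern present AND
[dye]_air > LoD. Either criterion alone is insufficient — the bundled
campaign contains above-LoD samples with no pattern (false-positive
guards) and pattern-bearing samples below the LoD.

## Source attribution

Per dye map falling inside a sampling interval:

* **Wind** is linearly interpolated to the map time on Cartesian (u, v)
  components, then converted back to speed/direction, so interpolation
  crosses the 0°/360° wrap correctly. No lag between wind and source
  times is applied: at ~5 m/s a parcel crosses the ~1.5 km to the
  farthest sampler in ~5 minutes, negligible against multi-hour
  sampling intervals. Extrapolation beyond the station record is
  refused.
* **Shoreline** is the contour of terrain elevation equal to the
  concurrent water level (tides included, wave set-up neglected),
  extracted with `skimage.measure.find_contours`; the longest contour
  piece is taken as the open-coast shoreline.
* **Upwind intersection** casts a ray from the site toward the wind's
  FROM-direction and keeps the nearest crossing with the shoreline
  polyline — the first shore encountered upwind. Offshore-directed
  winds produce no crossing and contribute no window.
* **Window** is 200 m alongshore × 100 m offshore, centred at the
  intersection, axes aligned to the local shoreline tangent (the only
  well-defined meaning of alongshore/offshore on a curved shoreline),
  extending seaward — the side away from the sampler. 100 m offshore
  reflects that sea spray is generated predominantly in the surfzone by
  depth-limited wave breaking. A 2 m cell belongs to the window when
  its centre lies inside the rectangle (unambiguous and
  oracle-checkable); the window mean ignores missing cells.
* **Aggregation**: [dye]_sea is the unweighted mean over maps of
  per-window spatial means; downwind distance is the mean straight-line
  distance from window centres to the site; inland distance is the
  minimum distance from the site to the datum (water level 0)
  shoreline, so it is a fixed site property while downwind distance
  varies with the winds. Intervals with no windows (night-time — the
  dye maps are daylight-only — or persistently offshore winds) carry
  missing [dye]_sea and downwind values and are excluded from, not
  zero-filled into, averages.

## Reporting

Wind roses use 16 sectors of 22.5° centred on north, speed classes
0–2 / 2–4 / 4–6 / >6 m/s, and a separate calm fraction below 0.5 m/s;
sector/class frequencies plus the calm fraction total 100%. The results
table join is validated one-to-one on sample id; rendered output wraps
air concentrations of non-detections in parentheses while the
machine-readable CSV keeps plain numbers plus boolean flags. Day/night
period labels for synthetic samples follow the sampling schedule
(daytime ~6 h, overnight ~15 h).

## Synthetic campaign generator

The generator emulates the statistical structure the analysis assumes,
not coastal hydrodynamics:

* **Beach**: planar, slope 0.02 (a typical steep-ish sand beach), ocean
  west of a straight north–south datum shoreline. The tidal shoreline
  excursion is exactly η/slope, making the geometry analytically
  checkable.
* **Tide**: sinusoid, amplitude 0.8 m, period 12.42 h (M2).
* **Wind**: mean 5 m/s from 270° (onshore for this layout) — the
  low-to-moderate regime in which surfzone SSA production dominates —
  with a 2 m/s diurnal (sea-breeze-like, afternoon peak) modulation,
  Gaussian speed jitter 0.5 m/s and direction jitter 12°, sampled every
  10 min.
* **Plume**: alongshore Gaussian with variance σ₀² + 2Kt (σ₀ = 50 m,
  K = 1 m²/s, a typical surfzone horizontal diffusivity), advected at a
  steady 0.03 m/s alongshore current; cross-shore, a half-Gaussian
  surfzone profile (width 100 m) hugging the instantaneous shoreline.
  The cross-shore profile is numerically normalised to unit integral,
  so grid-integrated mass is conserved exactly until the plume reaches
  an alongshore boundary. Rasterised at 2 m × 2 m, hourly, daylight
  hours only (08–17 h), matching an airborne imaging platform.
* **EEMs**: tracer signal is a bivariate Gaussian at 558/582 nm
  (σ 10/12 nm), exactly linear in concentration at 120 raw units/ppb;
  plus a constant offset (50), a water-Raman ridge (amplitude 400,
  σ 6 nm along the 3400 cm⁻¹ shift), a weak broad ambient-fluorophore
  hump (amplitude 15 at 450/530 nm) in samples and blanks but not in
  standards, and additive Gaussian noise (σ = 1 raw unit, giving a
  ~2% round-trip error at 0.5 ppb). Noise is additive Gaussian because
  nothing in the problem constrains a more elaborate error model and it
  keeps every recovery test interpretable.
* **Coupling truth**: each sample's true air concentration is
  k·[dye]_sea·exp(−downwind/L) with k = 200 pg·m⁻³ per ppb (the order
  of magnitude implied by the bundled campaign's detected ocean–air
  pairs) and L = 500 m (consistent with detections out to ~700 m
  downwind); [dye]_sea here is the window average computed by the same
  attribution geometry the pipeline uses, which is what makes k exactly
  recoverable when decay is disabled. Night samples, having no
  concurrent maps, get truth 0.
* **Determinism**: a fixed seed makes every generated artefact
  bit-identical across runs; all randomness flows from one
  `numpy.random.Generator`.

What passing the synthetic tests does *not* show: robustness to rip
currents, wave-driven alongshore variability, estuarine outflow, curved
or interrupted shorelines, scatter-line artefacts (Rayleigh ridges) or
inner-filter effects in real EEMs, or atmospheric dispersion beyond a
single exponential decay length. The generator is a correctness
harness, not a coastal model.

## Problem sizes and numerical choices

The default synthetic campaign covers 3 km of coast (2 m dye cells,
10 m terrain cells), 2 days, 3 sampler sites, ~20 hourly maps; the
transfer-recovery configuration uses 1 day and 8 near-shore sites
spanning the plume path so attributed source concentrations span more
than a 10× range. These sizes keep a full test run around ten seconds
while leaving every geometric path (night gaps, offshore winds, tidal
excursion) exercised.

Tolerances: quantitation round trip is required within 5% over
0.5–10 ppb at default noise; transfer-coefficient recovery within 10%;
window means must match a brute-force cell enumeration exactly (same
membership rule, floating-point tolerance 1e-12). Degenerate inputs are
errors, not silent defaults: empty wind series, all-equal calibration
concentrations, non-positive Raman areas, water levels outside the
terrain range, zero wind speed for an upwind ray. Directions returned
by component-space conversion are wrapped into [0, 360) with an
explicit guard against the floating-point `mod` returning 360 exactly.

## Known limitations

* The shoreline tangent is estimated from a ±2 m chord of the contour
  polyline; on contours with sub-cell-scale wiggles the window
  orientation inherits that noise.
* Attribution treats each map independently; no temporal weighting
  within an interval (maps are assumed evenly spaced).
* The parenthesis convention in rendered tables encodes only the joint
  detection outcome, not which criterion failed; consult the flag
  columns for that.
* `liquid_to_air_mass` assumes complete transfer of airborne tracer
  into the collection liquid; collection efficiency is not modelled.
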