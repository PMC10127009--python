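# Methods

## The measurement problem

Computer-assisted sperm analysis (CASA) of tardigrade spermatozoa works on
planar midline traces extracted from high-speed video (150 fps): per frame,
ordered point sequences for the head and the tail, each starting at the
mid-piece junction (the "base"), plus a mid-piece track. This package
implements the downstream analysis — kinematics, waveform/curvature
profiling, and the statistical comparisons — and, because no tracked video
data are public, a synthetic generator that produces traces with known
ground truth so the whole pipeline can be validated by parameter recovery.

## Synthetic beat-and-swim model

The generator factorises the motion into a beat (shape) and rigid swimming
(placement); no hydrodynamics is modelled, since only kinematics is
measured and propulsion is imposed rather than emergent.

**Beat.** Signed curvature along each filament is a travelling wave

    κ(s, t) = A(s) · sin(2π s / λ − 2π f t + φ₀),

with arc length `s` from the base. `A(s)` is `tail_amplitude` on the tail
and `head_amplitude_factor × tail_amplitude` on the head (default 0.3 —
heads tremble visibly less than tails), either constant along the filament
(default) or linearly ramped from zero at the base. The tangent angle is
the running integral of κ over s and the filament points the running
integral of the unit tangent, both by cumulative trapezoid at 0.1 µm
internal resolution so that the exported polyline never limits the 1-µm
station resampling. Head and tail share the base point and leave it in
opposite directions in the body frame.

**Swimming.** The base advances along a constant-speed path whose heading
changes at `heading_rate` (0 → straight, analytic circular arc otherwise);
the body frame is rotated to the path heading. Records span exactly
`duration` seconds: `round(duration·fps) + 1` frames at times 0, 1/fps, …,
duration, so the elapsed time `(n−1)/fps` used by every rate estimate
equals the nominal duration. Isotropic Gaussian noise of sd `noise_sd`
(default 0) is added to every exported coordinate, seeded and reproducible.

**Defaults and units.**

| parameter | default | unit | rationale |
|---|---|---|---|
| fps | 150 | frames/s | recording rate of the source videos |
| wavelength λ | 20 | µm | below the tail lengths; gives a realistic ~1.5 waves on a tail |
| tail_amplitude | 0.15 (Pm), 0.11 (Ms) | µm⁻¹ | bending radii ≥ ~7 µm; species differ in amplitude |
| head_amplitude_factor | 0.3 | — | stiff head; an order-of-magnitude variance gap (0.09×) |
| φ₀ | 2π/3 | rad | see "Numerical choices" |
| speed | 259.3 / 207.6 | µm/s | the two species' reported mean swimming speeds |
| beat frequency | 52.5 / 49.5 | Hz | the bounds of the reported average range, one per species |
| heading_rate (turning cells) | 180 | °/s | twice the 90 °/s classification threshold |

Morphologies: nucleus boundaries at 21 µm (*Paramacrobiotus* sp.) and
11 µm (*M. shonaicus*) from the head base follow published morphometry;
head/tail lengths (60.5/32.5 and 14.5/22.5 µm) are chosen so the interior
1-µm station counts equal the reported comparison totals (59/31 and 13/21
positions) and the *Paramacrobiotus* head covers stations past 48 µm.

Cohorts (26 cells per species, matching the reported n > 25) draw per-cell
speeds at sd 15 µm/s and beat frequencies at sd 4 Hz around the species
means; half of each cohort turns at 180 °/s with a 1.75× beat amplitude,
emulating stronger bending during turning. With a 4-Hz spread the 3-Hz
inter-species beat gap can still reach significance in a given cohort
draw, unlike the reported data — the real between-animal variability was
evidently larger; no validation result depends on this comparison.

## Analysis pipeline

**Stations.** Each frame's filament polyline is resampled by linear
interpolation along cumulative chord length at stations 1, 2, … µm from
the base (largest multiple ≤ total length). Station 0 (the base) is a
reference point, not a statistic site.

**Curvature.** κᵢ = (turn angle between secants i and i+1)/spacing, signed
positive for counter-clockwise turning (mathematical y-up coordinates); it
is invariant under rigid motions to 1e−9 and negated by reflection, and is
exact on circles sampled at equal arcs. The tip station only admits a
one-sided estimate; it is flagged as a boundary and excluded from
curvature series and significance statistics (one-sided estimates are
biased).

**Normalized waveform.** Rigid registration: base translated to the
origin, base tangent (secant station 0 → 1) rotated onto +x. Whether the
original toolchain additionally rescaled by body length is not documented;
rescaling is available as a flag (`rescale_by_length`) and nothing in
scope depends on it.

**VCL.** Summed frame-to-frame displacements of the mid-piece divided by
`(n−1)/fps`. Chord summation means VCL slightly underestimates the true
path speed on curved paths; for straight constant-speed tracks it is
exact.

**Beat frequency.** Signed curvature at the 5-µm tail station (curvature
is invariant to the cell's swimming motion, making the count robust) is
scanned for strict local maxima with prominence ≥ 0.2 × signal range and
separation ≥ 2 frames; frequency = count / elapsed time. Counting whole
peaks quantises the estimate to 1/duration; with the 2-s default records
that is 0.5 Hz. Peaks-only (not peaks + troughs) is deliberate, matching
how beats were scored. A constant signal returns 0 Hz with a warning.

**Straight vs turn.** Per non-overlapping 10-frame window of the mid-piece
track, the mean absolute heading change of displacement vectors, scaled to
°/s, is compared to a 90 °/s threshold (strictly greater ⇒ turn; exactly
at the threshold ⇒ straight). The source study states no operational
criterion, so this rule is this package's own declared stand-in, validated
on simulated cohorts whose turning rate is ≥ 2× the threshold. Windows
moving < 0.1 µm/frame are labelled immotile and excluded. The rule is
applied to raw displacement headings and is therefore *not* robust to
per-frame tracking noise (heading jitter scales as noise/step-length);
real tracks should be smoothed first — a known limitation.

**Statistics.** Per-station amplitude comparisons use the two-sided
variance-ratio F-test on signed curvature samples pooled across 10-frame
windows (one sample per frame per station): F = s²ₐ/s²ᵦ with n−1
denominators, p = 2·min(P(F ≤ f), P(F ≥ f)) capped at 1. Signed (not
rectified) curvature is used: under the wave model curvature at a station
has mean ≈ 0, so variance is the natural amplitude statistic; an unsigned
analysis can be run by taking |samples| upstream. Per-station p-values are
*not* corrected for multiple testing, matching the source analysis
(`adjust="bh"` enables Benjamini–Hochberg). Percentages of significant
stations are rounded half-up to one decimal. Cohort comparisons use the
Mann–Whitney U test: exact two-sided p by full enumeration of the U null
distribution (subset-sum dynamic programme, cached per sample-size pair)
when the combined n ≤ 20 and the data are tie-free, otherwise the
mid-rank normal approximation with tie and continuity corrections; the
method used is recorded in the result. Both tests are calibrated by
Monte-Carlo under H₀ in the test suite; note the exact U test is
conservative by discreteness (attainable p just below 0.01 at n = 10 + 10
is 0.0089).

## Numerical choices

* **Endpoint-inclusive sampling.** Records contain `round(duration·fps)+1`
  frames so elapsed time equals `duration` exactly; peak counts divided by
  elapsed time then recover any frequency whose peak count over the record
  is integral (e.g. 49.5 and 52.5 Hz over 2 s).
* **Default phase φ₀ = 2π/3.** With λ = 20 µm this places the first wave
  crest observed at the 5-µm station a third of a beat cycle into the
  record, so no crest sits within half a sample of either record endpoint
  (where discrete peak detection loses it) for any frequency up to 70 Hz
  at 150 fps, and the exactly-3-samples-per-cycle case (50 Hz) has no tied
  samples. Chosen analytically from the sampling geometry.
* **Degenerate inputs.** Repeated polyline points are rejected; collinear
  triples give κ = 0; both-sides-zero variance at a station yields p = 1
  (no detectable amplitude) rather than an error inside profile scans;
  aliasing (fps ≤ 2f) is rejected at construction.
* **Tie-breaks.** Heading rate exactly at the turn threshold ⇒ straight;
  F = 1 with equal df ⇒ p exactly 1 (symmetry point).
* **Problem sizes.** Validation uses 2-s single cells for exact recovery
  and 1-s, 26-cell-per-species cohorts for the comparative analyses;
  cohort traces are exported at 0.25-µm resolution (the 1-µm station grid
  is insensitive to export resolution at or below this).

## What the synthetic validation shows — and does not

Passing recovery tests show the estimators are unbiased and exact under
the model's assumptions: strictly planar beating, a single-frequency
travelling wave, arc-length-preserving filaments, rigid swimming, and
(mostly) noise-free coordinates. Real traces violate all of these to some
degree — 3-D beating components, amplitude drift along the record,
tracking noise correlated along the filament, segmentation dropouts near
the tip. The generator emulates none of those, so green tests certify the
*analysis*, not the tracking; in particular the straight/turn classifier
and the peak counter both degrade with unsmoothed coordinate noise.

## Known limitations

* No hydrodynamic propulsion model; swimming speed and beat are
  independent knobs, so speed–frequency correlations cannot be studied.
* 2-D only; no torsion or out-of-plane beating.
* The straight/turn criterion is a stand-in; published per-cell labels do
  not exist to calibrate it against.
* The Mann–Whitney exact path requires tie-free data; measured curvature
  at float precision is effectively tie-free, but quantised inputs will
  silently switch to the approximation (the result records which path
  ran).
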