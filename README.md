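# tardisperm

Kinematic and statistical analysis of tardigrade spermatozoon motility.

Tardigrade sperm are unusual cells: an elongated head carrying a coiled
nucleus and a long acrosome, a mid-piece, and a tail — and the cell swims
*mid-piece first*. This package analyses planar midline traces of such
cells (as produced by video tracking at 150 fps) and answers the questions
a sperm-motility study asks:

* **Curvilinear velocity (VCL)** of the tracked mid-piece,
  `VCL = Σᵢ ‖xᵢ₊₁ − xᵢ‖ / ((n−1)/fps)`.
* **Beat frequency** by counting curvature-wave peaks at the 5-µm tail
  station and dividing by elapsed time.
* **Waveform and curvature profiling**: each filament (head, tail) is
  resampled at 1-µm arc-length stations from its base; signed curvature at
  station *i* is the turn angle between consecutive unit secants divided by
  the spacing, κᵢ = Δθᵢ/Δs (exact in the circle limit).
* **Straight-vs-turn classification** of mid-piece windows from the mean
  absolute heading-change rate.
* **Per-station amplitude comparisons**: two-sided variance-ratio F-tests
  on signed-curvature samples per station (`F = s²ₐ/s²ᵦ`, p = 2·min(P(F≤f),
  P(F≥f))), significance profiles at p < 0.01, and percent-significant
  summaries; cohort comparisons use a Mann–Whitney U test that is exact
  (full enumeration of the U null) for small tie-free samples.

Because the original videos are not public, the package ships a synthetic
flagellar-beat generator with known ground truth: a travelling signed
curvature wave `κ(s,t) = A(s)·sin(2πs/λ − 2πft + φ₀)` on head and tail
(the head's amplitude scaled down — heads tremble less than tails), rigid
swimming at an imposed speed and heading rate, 150-fps sampling, optional
coordinate noise. Every estimator is validated by recovering the
parameters the generator was given.

## Worked example

```python
from tardisperm import (simulate_sperm, single_cell_truth, compute_vcl,
                        station_curvature_signal, beat_frequency)

truth = single_cell_truth(species="Paramacrobiotus",
                          speed=259.3, frequency=49.5, duration=2.0)
trace, track = simulate_sperm(truth)
print(f"VCL  = {compute_vcl(track):.4f} um/s")
signal = station_curvature_signal(trace, station_um=5.0, part="tail")
print(f"beat = {beat_frequency(signal, trace.fps):.4f} Hz")
```

prints

```
VCL  = 259.3000 um/s
beat = 49.5000 Hz
```

i.e. the curvilinear velocity and the peak-counted beat frequency recover
the imposed swimming speed and beat frequency exactly on a noise-free
2-second record.

The `analysis/` scripts run the full study on synthetic cohorts (two
species × 26 cells; run them in order from the repository root):
`01_simulate_cohorts.py` builds the cohorts, `02_kinematics.py` measures
VCL/beat per cell and compares the species (the *Paramacrobiotus* cohort
comes out significantly faster, Mann–Whitney p < 0.01),
`03_curvature_significance.py` computes the per-station F-test profiles
(straight vs turning, head vs tail, species vs species), and
`04_recovery_report.py` summarises estimate-vs-truth deltas. Outputs land
in `results/`. The same pipeline is scriptable via the `tardisperm` CLI
(`simulate`, `analyze`, `report`, `experiment`).

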