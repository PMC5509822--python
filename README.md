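# astrofiu

Automatic detection and functional phenotyping of astrocytic Ca²⁺ units in
time-lapse fluorescence imaging.

Astrocyte Ca²⁺ activity is organized into *functionally independent units*
(FIUs): connected pixel groups — a soma, a process, or a microdomain — that
share one characteristic fluorescence time course up to per-pixel time lags
(intracellular Ca²⁺ waves propagate slowly, so distant parts of a unit fire
with delays comparable to the event duration) and noise. Hand-drawn ROIs and
neuron-oriented tools that assume within-cell synchrony both fail on such
data. `astrofiu` finds the units, learns each unit's curve with the
propagation lags modeled explicitly, quantifies the result statistically,
and extracts the standard functional readouts.

## Model

A movie `Y[i, j, t]` is modeled as

```
Y[i,j,t] = β₀[i,j] + Σₘ βₘ[i,j] · Xₘ[t − τᵢⱼ] + ε[i,j,t]
```

with `‖Xₘ‖₂ = 1`, `E[Xₘ] = 0`; each pixel belongs to at most one unit; the
support of each `βₘ` is connected; `ε ~ N(0, σ₀²[i,j])` i.i.d. over time.
The pipeline has three stages:

1. **Active-region detection.** Each pixel's curve is correlated with the
   mean curve of its eight neighbors; the Fisher z-transform
   `z = √(N−3)·atanh(r)` gives a per-pixel score that is standard normal
   under the null. The z-map is segmented by seeded region growing whose
   significance test is calibrated with the theory of *normal order
   statistics* — the growth procedure selects high-ranked pixels, so the
   null mean/variance of a candidate region's mean score are those of its
   rank-selected order statistics, not of an i.i.d. sample. This controls
   the family-wise false-positive rate near the chosen α on pure noise.
2. **Sequential unit learning.** Within each active region, one unit at a
   time: an EM-like alternation estimates the unit curve `Xₘ`, per-pixel
   integer lags τ (correlation scan around the lag of each pixel's
   breadth-first predecessor), loadings β and noise σ₀²; pixels are then
   scored for membership by `z = ½Φ⁻¹(Φᴷ(F(r_fit))) − ½F(r_res)` — the
   best-lag fit correlation (max-of-K corrected) *minus* the neighborhood
   correlation of the residuals, which flags pixels whose leftover signal
   belongs to a different, still-latent unit. The unit's mask is grown on
   that score map, accepted if significant, removed, and the search repeats
   until nothing significant remains. The number of units is emergent.
3. **Features.** From each unit's refined curve `Cₘ`: baseline F₀ (10th
   percentile), ΔF/F₀, event amplitudes, event frequency (inverse mean
   inter-peak interval), half-decay time T₀.₅, area (px and µm²), and the
   propagation speed from the spacing of the iso-lag wavefronts.

A ground-truthed synthetic movie generator (transient curves
`(t−t₀)e^{−(t−t₀)/η}`, irregular procedural unit shapes, constant-velocity
radial lag maps, boundary-fading loadings, SNR-controlled Gaussian noise)
and the matching evaluation metrics make every stage testable without any
real recordings.

## Worked example

```python
from astrofiu import SimulationConfig, simulate_movie, FIUDetector, \
    detection_metrics, attach_fidelities, compute_features

scene, movie = simulate_movie(SimulationConfig(n_fius=40, snr_db=5.0, seed=1))
det = FIUDetector(alpha=0.05).fit(movie)
print(f"{det.n_fius_} units detected")

report = detection_metrics([f.mask for f in det.fius_], scene.fiu_masks)
attach_fidelities(report, [f.refined_curve for f in det.fius_], scene.true_curves)
print(f"recall {report.recall:.3f}  precision {report.precision:.3f}  "
      f"mean fidelity {report.mean_fidelity:.3f}")

compute_features(det.fius_, pixel_size_um=movie.pixel_size_um,
                 frame_interval=movie.frame_interval_s)
f = det.fius_[0].features
print(f"unit 1: area {f.area_px} px, {f.n_events} events, "
      f"max dF/F0 {f.max_dff0:.2f}")
```

On this movie (a 128×128×100 synthetic field, 40 active units at 5 dB) it
prints:

```
39 units detected
recall 0.975  precision 0.923  mean fidelity 0.927
unit 1: area 47 px, 3 events, max dF/F0 5.91
```

i.e. 39 of the 40 ground-truth units are recovered with > 50% of their area,
and the learned Ca²⁺ curves correlate with the true ones at 0.93 on average.
(Amplitude estimates on small units at this noise level run somewhat high:
the 10th-percentile baseline is biased low by residual noise in the refined
curve.)

The same pipeline runs from the shell:

```bash
astrofiu simulate -o scene/ --snr 5 --n-fius 40 --seed 1
astrofiu run scene/movie.tif -o out/ --alpha 0.05
astrofiu evaluate out/labels.tif scene/ --curves-csv out/curves.csv
```

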