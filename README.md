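# rfmonitor

Analytics for unobtrusive RF monitoring of older adults in residential
settings, built around two pipelines:

1. **Adaptive STA/LTA radar detector.** A bedroom-mounted mmWave radar
   reports per-second motion energy (0–100) in nine range gates, for a
   micromovement channel (breathing-scale motion) and a macromovement
   channel (whole-body motion). The gates are aggregated into a normalized
   signal C(k) = (1/N) Σⱼ cⱼ(k)/100 and segmented by a short-term /
   long-term average detector with hysteresis:

   - activate when STA(t) > σ₁ and STA(t)/LTA(t) > σ₂,
   - deactivate when STA(t) < σ₃ and STA(t)/LTA(t) < σ₂,

   with STA a forward mean over T₁ = 30 s and LTA a backward mean over
   T₂ = 300 s. The thresholds adapt per day and per radar unit from the
   day's own STA statistics: σ₁ = p75(STA); σ₃ from a relative-slope rule
   on the STA ECDF (the first value where the ECDF derivative falls below
   α = 0.2 of its peak, falling back to p15); and σ₂ as a CFAR percentile
   q = 100·(1−PFA), PFA = 10⁻³, of the background STA/LTA ratio, computed
   on low-energy samples with ±Tg guard bands around candidate activity
   and clipped to [0.5, 10]. Applied to the micromovement channel this
   yields bedroom occupancy; to the macromovement channel, non-sedentary
   activity. Bathroom presence runs of ≥ 30 s are visits, split into
   nocturia vs daytime by a sleep window estimated from the bedroom light
   signal.

2. **Floor-plan-aware UWB trajectory pipeline.** Raw UWB tag positions
   (cm, ~1 Hz) are preprocessed against the floor plan (forbidden-zone
   relocation, door-routed filling of gaps < 60 s with inflated
   measurement covariance αᵣ = 4, corridor center-line snapping) and
   filtered with a 2D nearly-constant-velocity Kalman filter
   (q_proc = 100 cm²/s³, σ_meas = 10 cm). After each update the segment
   between consecutive posterior positions is tested against the wall
   set; a crossing triggers a partially constrained update via a modified
   gain (Lagrange multipliers) that forces the violating position
   component(s) onto a feasible target just inside the wall. Daily
   mobility metrics follow: habitual gait speed (median of v(t) = ‖v‖
   over walking samples), maximum gait speed (95th percentile), walked
   distance, and active/sedentary/monitored time with 5-min gap and
   charging-zone exclusions.

Because deployment data of this kind is not publicly deposited, the
package ships first-class synthetic generators (`rfmonitor.synthetic`)
for all four input streams — radar days, light series, a floor-plan
fixture, and UWB walks — with known ground truth, so every stage is
testable end to end.

## Worked example

```python
import rfmonitor as rf

# --- radar: detect occupancy on a synthetic day with known truth
frames, occ_truth, _ = rf.gen_radar_day(rf.RadarDaySpec(seed=1))
series = rf.aggregate_gates(frames, "micro")
result = rf.detect_day(series, rf.StaLtaConfig())
t = result.thresholds
print(f"sigma1={t.sigma1:.3f} sigma2={t.sigma2:.3f} sigma3={t.sigma3:.3f}")
truth = occ_truth.to_mask(series.start_time, len(series))
det = result.segments.to_mask(series.start_time, len(series))
print(f"IoU vs truth: {(truth & det).sum() / (truth | det).sum():.3f}")

# --- UWB: filter a noisy walk and summarize mobility
plan = rf.gen_floorplan_fixture()
track, _ = rf.gen_uwb_track(rf.WalkSpec(seed=1, dwells=[0, 300, 60, 0]), plan)
filtered = rf.filter_track(rf.preprocess(track, plan), plan, rf.KfConfig())
summary = rf.mobility_summary(filtered.states, plan, (8 * 3600, 22 * 3600))
print(f"habitual speed {summary.habitual_speed:.2f} m/s, "
      f"distance {summary.distance:.1f} m")
```

prints

```
sigma1=0.186 sigma2=1.084 sigma3=0.022
IoU vs truth: 0.999
habitual speed 0.39 m/s, distance 17.0 m
```

The adaptive thresholds land where the day's statistics put them (σ₁
just under the occupied-mode STA level, σ₃ just above the empty-room
baseline, σ₂ slightly above the unit background ratio), the detected
occupancy mask matches the planted schedule almost exactly, and the
filtered walk yields a sub-m/s habitual gait speed typical of an older
adult walking indoors.

A command-line interface mirrors the library:
`rfmon simulate radar|uwb|plan`, `rfmon radar-detect`, `rfmon uwb-track`,
`rfmon metrics`.

## Layout

- `src/rfmonitor/radar_energy.py` — gate aggregation and 1 Hz binning
- `src/rfmonitor/stalta.py` — adaptive STA/LTA detector
- `src/rfmonitor/occupancy.py` — visits, nocturia, occupancy summaries
- `src/rfmonitor/floorplan.py` — map model and geometric predicates
- `src/rfmonitor/uwb_preprocess.py` — map-aware track preprocessing
- `src/rfmonitor/kalman.py` — partially constrained NCV Kalman filter
- `src/rfmonitor/mobility.py` — gait and time-budget metrics
- `src/rfmonitor/synthetic.py` — ground-truth input generators
- `src/rfmonitor/pipeline.py`, `cli.py`, `config.py` — glue, CLI, config

See `docs/methods.md` for the modeling choices, parameters and known
limitations.
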