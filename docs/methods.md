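# Methods

This note documents the models behind `rfmonitor`, the parameters that
matter, the numerical choices, what the synthetic generators do and do
not emulate, and the known limitations.

## Radar occupancy pipeline

### Signal model

The radar module reports, once per second, the motion energy (0–100) in
N = 9 fixed range gates along its line of sight, separately for a
micromovement channel (sensitive to breathing-scale motion) and a
macromovement channel (whole-body displacement). Because occupancy
detection needs the *occurrence* of motion rather than its range, gates
are collapsed into one bounded signal C(k) = (1/N) Σⱼ cⱼ(k)/100 ∈ [0, 1].
Frames are binned to a strict 1 Hz grid (last sample wins inside a bin —
collisions are clock jitter at a nominal 1 Hz rate); seconds with no
frame stay missing and are excluded from every downstream statistic,
never imputed as zero energy.

### The detector

STA(t) is the forward mean of C over (t, t+T₁] and LTA(t) the backward
mean over (t−T₂, t]; near the record edges the windows shorten to the
available samples, and missing bins are excluded from the means. The
ratio is guarded, r = STA / max(LTA, ε), ε = 10⁻⁶. The state machine
starts OFF, activates when STA > σ₁ **and** r > σ₂, and deactivates when
STA < σ₃ **and** r < σ₂ — the conjunctions plus σ₃ < σ₁ give hysteresis.
Missing samples hold the current state; a missing run of at least T₂
seconds, however, splits the record into independent sub-records (an ON
segment is closed at the start of the run), since the long-term baseline
is no longer trustworthy across such a hole.

Defaults: T₁ = 30 s (the time scale of presence events), T₂ = 300 s
(slow baseline; T₂/T₁ = 10 is the conventional operating range for this
detector family).

### Adaptive thresholds

Computed once per day and per radar unit — no iteration:

- **σ₁ = p75(STA).** All percentiles in the package use linear
  interpolation between closest order statistics.
- **σ₃** by a relative-slope rule: the ECDF F of the day's STA is
  evaluated on a 512-point uniform grid over [min, max], its derivative
  taken by central finite differences, and σ₃ is the smallest grid value
  *strictly after* the slope peak where the slope drops to ≤ α·max,
  α = 0.2. This puts σ₃ just above the empty-room STA mode. If no
  crossing exists (degenerate or flat distributions) σ₃ falls back to
  p15(STA). The "strictly after the peak" restriction matters: the raw
  rule "smallest STA with low slope" would otherwise always pick the far
  left tail, where the ECDF is also flat.
- **σ₂** by a percentile CFAR rule on the ratio: the background set B
  keeps samples with STA < σ₃ after excluding ±Tg (default 60 s = 2·T₁;
  the guard length is a free parameter) around every region with
  STA > σ₁; σ₂ is the q = 100·(1−PFA) percentile of r over B with
  PFA = 10⁻³, clipped to [0.5, 10]. A stable 99.9th percentile needs on
  the order of 10/PFA points, so |B| ≥ 10 000 is required; below that the
  low-energy limit relaxes to max(σ₃, p35(STA)) (guards kept), and below
  1 000 points σ₂ is not updated (the fixed-baseline value 1.5 is used,
  flagged `not_updated`).
- **Hysteresis enforcement:** if the rules produce σ₃ ≥ σ₁, then
  σ₃ ← max(0, σ₁ − 0.05).

A fixed baseline (σ₁ = 0.25, σ₂ = 1.5, σ₃ = 0.08, identical for all
users and days) is provided for diagnostic comparison, together with
ΔT_occ (signed occupied-time deviation from a reference annotation, in
minutes) and N_trans (ON↔OFF transition count) over a 07:00–22:00
window.

Records shorter than T₂, or with fewer than T₂ usable samples, are
excluded: thresholds are not updated and no segmentation is attempted.

### Degenerate regime: background-only days

On a day with no activity at all, the STA distribution is unimodal, the
slope rule lands *above* p75, and the enforcement above floors σ₃ at 0
whenever σ₁ < 0.05. Deactivation (STA < 0) is then impossible and the
first coincidence of the two activation conditions — which the CFAR rule
allows at rate PFA — latches the day into a single ON segment. This is a
direct consequence of the published constants (Δ = 0.05 presumes an STA
scale set by genuine activity) and is reproduced faithfully; the
detector should not be trusted on records whose STA distribution has no
activity mode carrying at least ~25% of the mass (σ₁ must exceed the
background mode for the percentile rules to separate the modes).

### Occupancy analytics

Bedtime is the last light→dark transition between 18:00 and 24:00
followed by ≥ 60 min of sustained darkness; wake time the first
dark→light transition between 03:00 and 12:00 followed by ≥ 60 min of
sustained light. Sustains must fit inside the record. The dark/light
binarization threshold is a config value (default 10 intensity units);
no universal lux threshold exists. Bathroom presence runs of ≥ 30 s are
visits; a visit is nocturia iff its *start* lies in [bedtime, waketime)
(the rule for straddling visits is a package choice, flagged in output).
Missing presence is treated as absence with a logged gap note. All
interval arithmetic is half-open [start, end) in seconds, which makes
intersections exact and prevents double-counting boundary seconds.

## UWB trajectory pipeline

### Preprocessing (strictly in this order)

1. **Forbidden-zone relocation:** samples inside a forbidden polygon move
   to the nearest corridor point reachable by a purely vertical or purely
   horizontal displacement (ties: smaller displacement, then horizontal);
   if no axis-aligned move reaches a corridor, the Euclidean-nearest
   corridor point is used and flagged.
2. **Gap filling:** gaps shorter than 60 s are filled with samples on the
   integer-second grid strictly between the endpoints. If the straight
   endpoint segment crosses no wall and no forbidden zone, positions are
   linear; otherwise they follow the polyline through the door anchors
   connecting the endpoint zones (shortest door route: fewest doors, ties
   by total anchor distance), traversed at uniform speed by arc length.
   Inserted samples carry cov_scale = αᵣ = 4 (doubled measurement std).
   Gaps of 60 s or more stay missing. Gaps with no door route stay
   unfilled, with a warning.
3. **Corridor snapping:** samples inside a corridor polygon are projected
   orthogonally onto its center polyline (nearest point over the
   polyline's segments; ties keep the earlier segment). Snapping applies
   after filling, so interpolated samples are snapped too.

z is carried through untouched; the filter is 2D.

### The constrained filter

State X = (x, y, vx, vy), cm and cm/s. Dynamics: constant-velocity with
white-acceleration process noise of intensity q_proc = 100 cm²/s³, so the
per-step velocity change has std √(q_proc·Ts) = 10 cm/s at Ts = 1 s —
smooth indoor motion for a person walking at 40–60 cm/s. Measurements
observe position only, with σx = σy = 10 cm (line-of-sight accuracy of
the tag hardware class), inflated ×αᵣ for interpolated samples — both in
the update and in the innovation covariance used by the crossing logic.
Each continuous segment (split at gaps ≥ 60 s) initializes from its
first position with zero velocity and P₀ = diag(10², 10², 50², 50²)
(position trusted at measurement level; velocity unknown at the scale of
fast indoor walking). Steps with a non-nominal spacing dt rebuild A and
Q with Ts = dt.

After the standard update, the segment from the previous posterior
position to the new unconstrained posterior position is tested against
all walls (axis-aligned segments; oblique walls are rejected at load
time). The first crossed wall (or a simultaneous horizontal + vertical
pair at a corner) defines a linear equality constraint C X = d on the
violating position component(s), with the target equal to the wall
coordinate offset 2 cm toward the feasible (previous) side. The
constrained estimate uses the modified gain

    K̃ = K − D'(DD')⁻¹ D (X̂ − X̃)(VᵀS⁻¹V)⁻¹ VᵀS⁻¹,  D = I₄,

whose posterior X⁻ + K̃V equals the target state X̃ exactly (X̃ is the
unconstrained posterior with constrained position components replaced by
the targets; velocities untouched — the constraint construction fixes
only C X̃ = d and leaves the free components to the package, which keeps
them at their unconstrained values). The covariance follows the
associated quadratic-form update and is symmetrized. In rare geometries
the constrained position can still cross a *second* wall; the crossing
test is re-applied (up to 3 passes) with the constraint rows
accumulated, so the single modified-gain update always acts on the
original unconstrained posterior with the full stacked constraint.

Two numerical guards protect the gain formula, which scales as
1/(VᵀS⁻¹V):

- if VᵀS⁻¹V ≤ 10⁻² (innovation below ~0.1σ in Mahalanobis distance), the
  state is substituted directly (X = X̃) and the covariance uses the
  unmodified gain;
- if any entry of the gain correction exceeds 50, the same fallback
  applies. This covers *sustained* constraint conflicts — measurements
  persistently beyond a wall — where the modified-gain covariance
  recursion is divergent. The formulation is defined for isolated
  (event-wise) crossings; the guards keep long conflicts bounded without
  changing the state-level behavior.

Known limitation: an equality constraint keeps the estimate on the
previous posterior's side of the wall. If an adversarial measurement
sequence (e.g. an NLOS ghost exactly at a doorway passage) latches the
estimate on the wrong side while the person moves on, the estimate
slides along the wall until the true path re-crosses through a door
gap. The output remains wall-feasible throughout — the geometric
guarantee holds — but position error during such an episode is bounded
only by the room scale, and the velocity magnitude is unreliable there.

### Mobility metrics

v(t) = ‖(vx, vy)‖ in m/s from the posterior velocities. Walking samples
are v > 0.2 m/s — the same threshold splits active vs sedentary time, as
no separate walking threshold is defined. Habitual gait speed is the
median of v over walking samples, maximum gait speed the 95th
percentile; both undefined (flagged) with no walking samples. Distance
sums displacements between consecutive samples with both endpoint speeds
above threshold and spacing ≤ 5 min. Time budgets accumulate actual
inter-sample intervals in the 08:00–22:00 window, each labeled by the
state at its left endpoint; intervals longer than 5 min (strictly — a
4 min 59 s spacing still counts) are missing coverage and contribute to
no total; consecutive low-speed samples inside the charging zone whose
covered duration reaches 5 min are excluded from sedentary and monitored
time (device charging, not inactivity). Monitored = active + sedentary.

## Synthetic data: what it emulates, and what it does not

- **Radar days** (07:00–22:00 at 1 Hz): folded-normal per-gate clutter
  (micro location 2.0, macro 1.0, scale 1.0 on the 0–100 scale) plus
  scheduled bursts whose total energy (ΔC = 0.18 micro / 0.15 macro,
  i.e. the nominal 10:1 contrast over background, ±20% per-second
  jitter) is spread over three gates around a slowly wandering target
  position. Defaults plant 12 h of occupancy in the 15 h window with
  4.2 h (35%) of activity — a fairly active resident, consistent with
  the occupancy and activity fractions reported for real residents of
  this population, and inside the detector's working regime (the
  elevated STA mode must carry ≥ ~25% of the mass; see the degenerate
  regime above). Not emulated: slow clutter drift, multipath structure,
  gate-correlated noise, and transitional (partial-presence) seconds —
  so the near-perfect recovery IoU (~0.999) on synthetic days is an
  upper bound, not a field accuracy claim.
- **The floor-plan fixture:** two rooms, a corridor (100 cm wide, center
  line y = 250), a hall, a forbidden shaft flanking the corridor, a
  charging zone, and three 80 cm doorways with midpoint anchors.
- **UWB walks:** waypoint paths routed through door anchors —
  perpendicular doorway passes with 60 cm clearance points and a 2 s
  pause at each door, corridor spans along the center line — at
  50 cm/s, with isotropic N(0, 10²) noise per axis, optional NLOS
  outliers that displace a sample across the nearest wall within 100 cm
  (ghosts appear near walls), scheduled coverage gaps, and low-speed
  charging dwells. The perpendicular-door geometry is both how people
  walk and the regime the event-wise constraint handles well; diagonal
  corner-cutting through a doorway reproduces the latching limitation
  described above. Not emulated: gait micro-dynamics, heading-dependent
  NLOS bias, z variation.

Passing tests on these generators demonstrate the algorithms implement
their rules exactly and behave as designed under the stated noise
models; they do not validate field accuracy on real residents.

## Test and script problem sizes

The test suite exercises 20 seeded radar days (two background levels),
20 outlier-laden walks for the wall-feasibility guarantee, 200 random
series for the bit-exact STA/LTA oracle equivalence, 10⁶-sample draws
for CFAR calibration, and 1000 random instances for the
constrained-update identities. The acceptance script uses 5 radar days
and 5 walks per quantity; means over these are reported.
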