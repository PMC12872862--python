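# Methods

## The problem

Pressure-volume (PV) analysis is the reference framework for characterizing
left-ventricular (LV) pump function because it separates intrinsic myocardial
properties from loading conditions, but classically it requires an invasive
LV pressure catheter. `pvloops` implements a fully non-invasive single-beat
variant: the LV pressure waveform is *estimated* from brachial cuff
pressures, the mean transaortic gradient (relevant in aortic stenosis), and
the timing of the four valvular events, then paired with an
echocardiography-derived volume-time trace to form a PV loop and its derived
metrics.

## Pressure waveform estimation

A generic normalized LV pressure template `p_norm(phase)` on phase ∈ [0, 1]
(phase 0 = mitral valve closure / R-wave, phase 1 = cycle end) is
individualized by two operations:

1. **Horizontal (time) warp.** A strictly increasing piecewise-linear
   bijection maps the template landmark phases (MVC, AVO, AVC, MVO, cycle
   end) onto the patient's measured event times. Landmark images are exact;
   the template's peak is carried proportionally within the AVO→AVC segment
   (peak timing within ejection is not separately measurable from the inputs).
2. **Vertical (pressure) affine map.** `P = a·p_norm + b` with the two
   anchors
   * `P(peak) = SBP + mean gradient` (peak LV pressure; the gradient term is
     zero without outflow obstruction), and
   * `P(AVO) = DBP` (at aortic valve opening LV pressure equals aortic
     diastolic pressure).

The warped knots are interpolated with a monotone piecewise cubic (PCHIP),
which cannot overshoot the anchors, and resampled to a uniform grid (default
200 Hz). Values below a floor (default 2 mmHg) are clamped: the two-anchor
scaling makes no fidelity claim for the filling phase, and single-template
methods of this type are known to overestimate filling pressures when
systolic pressure is high. For the same reason the end-diastolic
pressure-volume relationship (EDPVR) is deliberately not modelled anywhere
in the package.

**Template shape.** The original averaged multi-patient template is not
publicly available, so the package ships a documented parametric stand-in:
raised-cosine (C1) segments through the landmark levels
(end-diastolic 0.12 → 0.45 at AVO → 1.0 at 45 % of ejection → 0.40 at AVC →
0.06 after relaxation → 0.12 at cycle end). Only the template *shape* is
free; the scaling contract above is what the estimation method specifies,
and a site-specific template can be supplied from CSV
(`load_reference_curve`). The estimated-pressure object exposes both the
uniform samples and the continuous curve; the anchoring contract holds
exactly on the curve (the landmarks are interpolation knots), while the
sampled maximum carries ordinary sampling error (~0.05 mmHg at 200 Hz).

## Loop construction and metrics

Traces are synchronized onto one shared uniform grid; if the two cycle
lengths differ by ≤ 5 % (configurable) the pressure time axis is linearly
rescaled to the volume cycle, otherwise the pair is rejected. The loop is
the implicitly closed polygon of paired (V, P) samples, normalized to
counter-clockwise traversal.

* **Stroke work** `SW = |shoelace area|` of the polygon (mmHg·mL).
* **End-systolic point**: volume and pressure are min-max normalized; among
  vertices strictly left of and above the vertex-mean center, the one with
  the greatest Euclidean distance from the center is chosen (ties → earliest
  acquisition time). The vertex mean (not the area centroid) defines the
  center; with uniformly sampled closed traces the two are
  indistinguishable in practice and the vertex mean is parameter-free.
* **Ees** `= ESP / (V_es − V0)` with the single-beat convention `V0 = 0 mL`.
  With a true positive V0 this is a strict lower bound on the true slope —
  a property asserted on simulated beats.
* **Ea** `= ESP / SV`, **VAC** `= Ea / Ees`, `SV = EDV − ESV` with EDV/ESV
  the cycle's volume extrema (the end-systolic *vertex* volume is used for
  Ees and PE; the volume minimum is used for SV — the two can differ by a
  sample).
* **Potential energy** `PE = ½ · ESP · (V_es − V0)`: the triangle between
  the ESPVR, the isovolumic relaxation line, and a zero EDPVR. With the
  EDPVR unmodelled this is the only self-consistent single-beat reading of
  the usual PV-area diagram; published cohort PE means computed by other
  conventions are not expected to be reproduced in absolute terms, but the
  identity `PVA = SW + PE` (which the published means satisfy exactly) is
  preserved by construction.
* **Efficiency** `= 100·SW/PVA`; single-beat contractility ratios
  `ESP/EDV` and `Pmax/EDV`.

## Myocardial work

Segmental pressure-strain work is the integral of `P(t)·(−dε/dt)` (mmHg·%)
from MVC to MVO, with centered finite differences for `dε/dt`. Shortening
during systole (MVC→AVC) is constructive, systolic lengthening wasted;
during isovolumic relaxation (AVC→MVO) lengthening is constructive and
post-systolic shortening wasted. GWI is the mean net work over segments,
GCW/GWW the mean components, and `GWE = 100·GCW/(GCW+GWW)`. No validity
mask is applied to segments; callers exclude untracked segments upstream.

## Agreement statistics

Single-rater ICCs are computed directly from ANOVA mean squares: ICC(1,1)
(one-way random, intraobserver designs), ICC(2,1) (two-way random, absolute
agreement, interobserver designs), ICC(3,1) consistency (two-way mixed).
Zero between-subject variance returns a defined (≤ 0) value with a warning
rather than an error. Bland-Altman limits of agreement are always
`bias ± 1.96·SD` (multiplier configurable); OLS and paired t / Wilcoxon
tests delegate to SciPy.

## The simulator

The synthetic-beat generator is kinematic: volume is a prescribed waveform
(cosine ejection and filling limbs between exact isovolumic plateaus, so
`EDV − min V = SV` holds exactly) and pressure follows a time-varying
elastance model `P = E(t)·(V − V0)` with a double-Hill `E(t)` whose maximum
is tied to aortic valve closure — maximal elastance at end-ejection, which
is also the internal oracle for end-systolic detection. Stenosis is an
instantaneous gradient `k·Q²` on the analytic half-sine ejection flow, so
the mean gradient has the closed form `k·(SV·π/2Te)²/2`, inverted to target
a requested gradient. Cuff pressures are the central aortic extremes (no
peripheral amplification): systolic = peak aortic pressure, diastolic =
LV (= aortic) pressure at AVO.

Default beat: EDV 172 mL, SV 93 mL (EF 54 %), E_max 2.7, E_min 0.08
mmHg/mL, V0 10 mL, cycle 0.9 s (67 bpm), ejection from 7 % to 40 % of the
cycle, mean gradient 51 mmHg — a severe-AS patient with preserved EF. The
double-Hill shape constants (n₁ = 1.3, a₁ = 1.0, n₂ = 21.9, a₂ = 0.508 on
peak-normalized time) were set so the default beat reproduces that
population's pressure signature: diastolic cuff ≈ 73 mmHg, end-diastolic
pressure ≈ 13 mmHg, and end-systolic pressure within ~3 % of peak systolic
pressure (the cohort-mean ESP/EDV : Pmax/EDV ratio). Cohort draws are
uniform over EDV 140–210 mL, EF 0.45–0.62, E_max 2.0–3.4 mmHg/mL,
E_min 0.05–0.12 mmHg/mL, V0 0–15 mL, cycle 0.7–1.1 s, and target mean
gradient 30–80 mmHg; parameter combinations the circulation cannot sustain
(gradient driving aortic pressure non-positive) are rejected and redrawn,
deterministically under the seed.

What the simulator does *not* emulate: measurement noise, frame-rate limits
and RR-variability of 3D echo, peripheral-to-central cuff transfer,
valve dynamics, atrial mechanics, or heart-rate dependence of elastance.
Passing recovery tests therefore demonstrate the *pipeline's* correctness
under ideal signals at clinical scale, not clinical accuracy.

## Problem sizes and numerical choices

The validation experiments use 50-beat cohorts at 200 Hz (≈ 180 samples per
beat) — comfortably more beats than the 16-patient invasive validation they
mirror, at the same per-beat resolution. Loop areas use the shoelace
formula (exactly the cyclic trapezoid ∮P dV on paired samples); detection
ties are broken to the earliest time; interpolation is PCHIP throughout to
avoid overshoot near anchors and plateaus; all randomness flows through a
single `numpy` generator seeded by the caller.

## Known limitations

* Absolute PE (and hence PVA/efficiency) depends on the `V0 = 0`, zero-EDPVR
  convention; values are comparable within the convention, not with
  catheterization-laboratory multi-beat analyses.
* The estimated waveform's diastolic limb is a template artifact; filling
  indices must not be derived from it.
* The end-systolic detector assumes a loop with a discernible upper-left
  corner; loops whose pressure falls far below its systolic plateau before
  aortic closure (ESP ≪ Pmax) can defeat the normalized-distance heuristic.
* `simulate_cohort` redraws inadmissible parameter combinations, so the
  realized joint distribution is the uniform box truncated to sustainable
  circulations.
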