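# pvloops

Fully non-invasive left-ventricular (LV) pressure-volume loop analysis.

Pressure-volume (PV) loops characterize ventricular function *including* the
loading conditions that ejection fraction and strain ignore, but classically
require an LV pressure catheter. `pvloops` implements a clinically oriented
single-beat alternative for patients with or without aortic stenosis (AS):

1. **Pressure estimation** — a generic normalized LV pressure template is
   warped in time to the patient's measured valve events (MVC, AVO, AVC,
   MVO) and scaled by the affine map anchored at
   `P_peak = SBP + mean transaortic gradient` and `P(AVO) = DBP`
   (cuff pressures from a sphygmomanometer; the gradient from CW Doppler,
   zero without outflow obstruction).
2. **Loop analysis** — the estimated waveform is synchronized with a
   3D-echo volume-time trace; from the closed loop the package computes
   stroke work `SW = ∮P dV` (shoelace area), the end-systolic point
   (greatest normalized distance from the loop center in its upper-left
   region), end-systolic elastance `Ees = ESP/(V_es − V0)` with the
   single-beat convention `V0 = 0`, arterial elastance `Ea = ESP/SV`,
   ventriculo-arterial coupling `VAC = Ea/Ees`, potential energy
   `PE = ½·ESP·V_es`, pressure-volume area `PVA = SW + PE`, ventricular
   efficiency `100·SW/PVA`, and the single-beat ratios `ESP/EDV` and
   `Pmax/EDV`.
3. **Myocardial work** — pressure-strain loop indices (GWI, GCW, GWW, GWE)
   from segmental speckle-tracking strain traces and the estimated pressure.
4. **Method agreement** — Pearson r, ANOVA-based ICCs (one-way random,
   two-way random, two-way mixed consistency), OLS regression, Bland-Altman
   bias and limits of agreement (`bias ± 1.96·SD`), paired t / Wilcoxon.
5. **Simulation** — a time-varying-elastance ground-truth generator
   (`P = E(t)·(V − V0)`, double-Hill `E(t)`, quadratic stenotic gradient
   `k·Q²`) for validating the whole pipeline by parameter recovery without
   patient data.

See `docs/methods.md` for the model details, parameter defaults, and
limitations.

## Worked example

Simulate a severe-AS beat and analyze it with the cohort-typical
non-invasive inputs (cuff 159/73 mmHg, mean gradient 51 mmHg, valve events
from echo):

```bash
python -c "
from pvloops.simulator import simulate_beat, SimParams
from pvloops.trace_io import write_trace
write_trace(simulate_beat(SimParams()).volume, 'volume.csv')"

pvloops pvloop --volume volume.csv \
  --systolic 159 --diastolic 73 --mean-gradient 51 \
  --mvc 0 --avo 0.063 --avc 0.36 --mvo 0.45 --cycle-length 0.9 \
  --out-dir results/
```

prints (and writes to `results/pv_metrics.{json,csv}`):

```json
{
  "sw": 16673.83117254112,
  "pe": 12901.767786377788,
  "pva": 29575.598958918905,
  "ees": 1.6841711824588432,
  "ea": 2.241556942261389,
  "vac": 1.3309555261412191,
  "efficiency": 56.376985621496296,
  "esp": 208.4647956303092,
  "v_es": 123.7788639311334,
  "edv": 172.0,
  "esv": 79.0,
  "sv": 93.0,
  "esp_over_edv": 1.2120046257576116,
  "pmax_over_edv": 1.2206282635317975,
  "v0": 0.0
}
```

Reading the numbers: the peak estimated pressure is 159 + 51 = 210 mmHg;
the loop encloses 16,674 mmHg·mL of stroke work and stores 12,902 mmHg·mL of
potential energy at end-systole, so 56 % of the total pressure-volume area
(29,576 mmHg·mL) is delivered as external work. Coupling `VAC = 1.33` and
the contractility ratio `ESP/EDV = 1.21 mmHg/mL` are in the range reported
for severe-AS cohorts with preserved ejection fraction.

Other workflows:

```bash
pvloops simulate --n 50 --seed 1 --out-dir cohort/    # synthetic cohort
pvloops validate --manifest cohort/manifest.json      # estimated vs true pressure
pvloops compare-visits --baseline pre/manifest.json \
                       --followup post/manifest.json  # paired visit changes
pvloops mwi --strain strain.csv --systolic 159 --diastolic 73 \
  --mean-gradient 51 --mvc 0 --avo 0.063 --avc 0.36 --mvo 0.45 \
  --cycle-length 0.9                                  # myocardial work
```

All commands also accept `--config config.yaml` (keys `systolic_mmHg`,
`diastolic_mmHg`, `mean_gradient_mmHg`, `events: {mvc, avo, avc, mvo,
cycle_length}`, `sample_rate_hz`, `reference_curve`), and a site-specific
reference template can replace the built-in one via `--reference-curve`.

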