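# fifplan

Automated forward planning for rectal-cancer 3DCRT: rule-based field
apertures plus an iterative field-in-field (FIF) algorithm with beam-weight
optimization, exercised end-to-end on synthetic pelvis phantoms with a
simplified divergent-beam dose engine standing in for a commercial treatment
planning system.

The toolkit is aimed at medical-physics researchers who want a
self-contained, fully testable model of the clinical 3DCRT workflow —
aperture placement from bony landmarks and tumor volumes, wedges, subfield
blocking, quadratic weight optimization, dose normalization — without
needing patient data or a TPS license.

## The workflow

A 3-field plan (posterior–anterior `PA` plus opposed laterals `LT`/`RT`)
is built from clinical border rules applied in the beam's eye view (BEV):

* **PA field** — superior border at the L5/S1 junction or 2 cm above the
  GTV/GTVn (whichever is more superior); inferior border at the obturator
  foramen bottom or 3 cm below the GTV (whichever is more inferior); lateral
  borders 2 cm beyond the pelvic brim; corner blocks spare the sacroiliac
  joints and femoral heads.
* **Laterals** — superior/inferior borders copied from the PA field;
  posterior border 1 cm behind the sacrum; anterior border 3 cm anterior to
  the sacral promontory or 2 cm anterior to GTV/GTVn (whichever is more
  anterior). The right lateral is built first; the left is its mirror image.
* **Boost laterals** — convex hull of the 2 cm-expanded GTV ∪ GTVn extended
  posteriorly to 1 cm behind the sacrum, with 15° wedges.

Dose is normalized by global rescaling (Eq. below left): every voxel dose
`D_i` is mapped to `Rx · D_i / D_p`, where `D_p` is a point dose or a
dose-volume percentile (by default the dose covering 99% of the pROI — the
planning surrogate built by eroding the region of high dose, RHD, by 1 cm).
Beam weights `α_j` (fractions of total MU) minimize a one-sided quadratic
objective (below right) under box constraints:

    D_i → Rx · D_i / D_p            f(α) = Σ_m ω_m Σ_{i∈ROI_m} [D_i − D_m^Rx]_±²,
                                    D_i = Σ_j α_j B_ij,
                                    minMU/totalMU ≤ α_j ≤ maxMU/totalMU

with targets penalized only below their level, OAR-like flank/anterior
regions only above a tolerance, and the RHD only above the hotspot level.
`B_ij` is the per-beam dose per unit weight from the surrogate engine
(radiological-depth exponential falloff past a 25 mm build-up, inverse
square, MLC transmission, linear wedge profiles).

The **FIF loop** then repeats: renormalize → measure the *hotspot dose
percentage* (the highest threshold at which a fully connected ≥ 8 cm³
supra-threshold volume still exists) → optimize weights → project the
hotspot (distally truncated) into a lateral BEV and block it with the
nearest MLC bank, creating one subfield per iteration on alternating sides.
It stops when (1) the target percentage (default 107% of Rx) is reached,
(2) the subfield budget (default 6) is exhausted, or (3) a subfield makes
the hotspot worse, in which case it is removed again.

## Worked example

```
fifplan run --seed 0 --out out/
```

or equivalently from Python:

```python
from fifplan.workflow import RunConfig, run_end_to_end
report = run_end_to_end(RunConfig())
```

On the reference phantom (45 Gy / 25 fractions, 60° lateral wedges,
2.5 mm grid) this prints a report whose key numbers are:

```
"hotspot_percent_before": 113.43,   # hottest connected 8 cm3, % of Rx
"hotspot_percent_after":  106.77,   # after FIF: at or below the 107% target
"v107_proi_before": 26.772,         # % of pROI above 107% of Rx
"v107_proi_after":   0.186,
"n_subfields": 1, "termination_reason": 1,
"weights": [0.396, 0.272, 0.300, 0.032],   # PA, LT, RT, subfield
"proi_metrics": {"V100_pct": 99.0009, "D99_Gy": 45.0, "max_Gy": 48.353},
"boost": {"coverage_percent": 98.012, "boost_volume_cm3": 1035.92}
```

Reading: the initial 2:1:1 wedged plan carries a posterior hotspot of
113.4% of the prescription; one blocking subfield on a lateral plus weight
re-optimization brings the hottest connected 8 cm³ to 106.8% (termination
condition 1: target reached), while the prescription still covers 99% of
the pROI (`V100_pct`). The boost fields are then normalized so 98% of the
boost volume receives the 5.4 Gy boost prescription.

## Layout

| module | contents |
| --- | --- |
| `fifplan.grid` | voxel-grid container, Euclidean mask morphology, grid file format |
| `fifplan.phantom` | synthetic pelvis phantoms and analytic bony landmarks |
| `fifplan.geometry` | beams, BEV frame, ray-trace projection, DRR generation |
| `fifplan.apertures` | border rules, corner blocks, boost hull, MLC fitting, mirroring |
| `fifplan.dose` | surrogate dose engine, wedges, ROI algebra (RHD/pROI/LTRT/APPA), DVH metrics |
| `fifplan.optimize` | normalization, one-sided quadratic objective, bound-constrained solvers |
| `fifplan.fif` | hotspot analysis, subfield construction, the FIF loop, boost fields |
| `fifplan.workflow` / `fifplan.cli` | end-to-end orchestration, config I/O, exports, CLI |
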