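# droughtvigor

A Python pipeline for contrasting **declining (D)** and **non-declining
(ND)** conifers in drought-triggered forest die-off studies. It covers
the quantitative chain such studies rest on: tree-ring growth (basal
area increment), wood and bordered-pit anatomy, xylem vulnerability
curves, minimum leaf conductance, dual water-isotope source analysis,
carbon-isotope water-use efficiency, climate water balance and trends,
and the cohort-level statistics that bind them — plus a synthetic
cohort generator so the entire pipeline is testable end to end without
field data.

## The science in brief

Trees dying in hot droughts tend to fail hydraulically. The pipeline
quantifies the traits behind that failure:

- **Vulnerability curves.** Percent loss of conductance
  `PLC = 100·(1 − Ks/Kmax)` is fit against xylem pressure Ψ with the
  sigmoid `PLC(Ψ) = 100 / (1 + exp((s/25)(Ψ − P50)))`, giving the
  pressure at 50 % conductance loss (P50, MPa) and the slope s
  (% MPa⁻¹); P12/P88 follow analytically. Safety margin = Ψ_midday − P50.
- **Pit anatomy.** From aperture (Da), torus (Dt) and membrane (Dm)
  diameters: torus overlap `(Dt − Da)/Dt`, margo flexibility
  `(Dm − Dt)/Dm` and valve effect (their product) — the capacity of the
  torus to seal the pit during aspiration.
- **Minimum leaf conductance.** gmin (mmol m⁻² s⁻¹) from the linear
  (cuticular) phase of needle desiccation curves:
  `gmin = (−dm/dt / 18.015) / (A · Δw)` with
  `Δw = es(T)(1 − RH)/P` (Tetens).
- **Growth.** Basal area increment `BAI = π(r²_{t+1} − r²_t)`
  reconstructed outside-in from ring widths (Tucson .rwl supported),
  with 20-yr moving cross-dating correlations and per-year Wilcoxon
  rank-sum D-vs-ND comparisons.
- **Water sources.** δ¹⁸O/δ²H evaporation lines through soil and
  recharge waters; xylem offsets from the current line diagnose
  shallow vs deep (and stale vs current) water use.
- **iWUE.** Wood δ¹³C → discrimination
  `Δ = (δₐ − δ_w)/(1 + δ_w/1000)` → `Ci = Ca(Δ − a)/(b − a)` →
  `iWUE = 0.625·Ca(1 − Ci/Ca)` with a = 4.4 ‰, b = 27 ‰.
- **Climate.** FAO-56 Penman–Monteith reference evapotranspiration from
  reduced station data (Tmax/Tmin/P), annual water balance P − PET, and
  Mann–Kendall trend tests with Sen slopes.

## Worked example

```python
from droughtvigor.synthetic import CohortConfig, generate_cohort
from droughtvigor.cohort import run_report, render_report_text

cohort = generate_cohort(CohortConfig(seed=42))   # 15 trees per class
print(render_report_text(run_report(cohort)))
```

prints (abridged):

```
Cohort report (D = declining, ND = non-declining)

  D: 8/15 trees died over 5 yr -> 10.67 % yr-1
  ND: 1/15 trees died over 5 yr -> 1.33 % yr-1

  Expectation checklist:
    [OK ] dbh                expected D<ND, D=21.293 ND=26.627
    [OK ] gmin               expected D>ND, D=0.800 ND=0.613
    [OK ] p50                expected D>ND, D=-3.210 ND=-3.342
    [OK ] torus_overlap      expected D<ND, D=0.437 ND=0.497
    [OK ] valve_effect       expected D<ND, D=0.184 ND=0.237
    ...
  All expected contrasts match: True
```

Declining trees die an order of magnitude faster (10.67 vs 1.33 %
yr⁻¹), and every trait contrast comes out in the direction the
die-off model predicts: D trees are smaller, slower-growing, have
wider pit apertures (weaker valve effect), leakier cuticles (higher
gmin) and sit closer to their hydraulic limits. Each checklist row is
recomputed from the raw synthetic streams by the corresponding analysis
module (e.g. gmin by refitting the desiccation curves, P50 by refitting
every vulnerability curve).

The same is available from a shell:

```bash
droughtvigor simulate --seed 42 --out cohort/
droughtvigor report cohort/ --json-out report.json
droughtvigor fit-vc curves.csv      # and: bai, crossdate, pit, gmin,
droughtvigor climate station.csv --latitude 41.27 --elevation 961
```

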