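# inhibkit

In vitro enzyme-inhibitor characterization as a tested, reusable analysis
package: initial-rate extraction and IC50 dose-response fitting, inhibition
reversibility testing, mixed-inhibition kinetics via Lineweaver-Burk
secondary plots (Ki, Kis, inhibition-type call), fluorescence-quenching
binding analysis (inner-filter correction, Stern-Volmer Ksv/Kq with
static-vs-dynamic classification, double-log Ka and binding-site number),
and Van't Hoff binding thermodynamics (ΔH, ΔS, per-temperature ΔG,
driving-force classification). A seeded forward simulator generates every
input table the analyses consume, so the whole workflow is testable by
parameter-recovery round trips.

## Library quick tour

```python
from inhibkit import (
    KineticParams, NoiseModel, QuenchParams, TitrationScheme,
    simulate_rate_grid, lineweaver_burk_transform, fit_primary_lines,
    fit_secondary, simulate_titration, stern_volmer_fit, double_log_fit,
    binding_thermo,
)

p = KineticParams(vmax=1.0, km=10.0, ki=10.6, kis=57.24)  # μmol/L
table = simulate_rate_grid(p)                      # paper-style S×I grid
fit = fit_secondary(fit_primary_lines(lineweaver_burk_transform(table)))
fit.ki, fit.kis, fit.inhibition_type               # 10.6, 57.24, "mixed"

scheme = TitrationScheme(v0=2.0, va=0.1, c_stock=100.0, n_additions=8)
q = QuenchParams(f0=1000.0, ksv=1.881e5, ka=1.67e4, n=1.183)
series = simulate_titration(q, scheme, 298.0, mode="stern_volmer")
stern_volmer_fit(series).ksv                       # 1.881e5 L/mol
```

Concentrations are μmol/L throughout the API; Stern-Volmer, double-log and
Van't Hoff computations convert to mol/L internally (constants in L/mol).
Infinite inhibition constants (pure competitive/uncompetitive) are the
`inhibkit.INF` sentinel. IC50 standard errors come from the fit covariance;
aggregate replicate fits yourself if you want across-replicate SDs.

## CLI

```bash
inhibkit simulate --out data/                 # write all input CSVs
inhibkit kinetics --rates data/rates.csv --out out/
inhibkit activity --dose-response data/dose_response.csv \
                  --rates data/rates.csv --out out/
inhibkit quench --titration data/titration.csv --out out/
inhibkit thermo --quench-json out/quench_fit.json --out out/
inhibkit reproduce --out out/                 # full pipeline, built-in scenario
```

`reproduce` chains every stage on a JSON scenario (default: the reference
characterization) and writes `report.json` plus a per-temperature
`binding_summary.csv`. Reports are deterministic given scenario + seed.

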