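# pemriver

Water-quality, ecological-risk and human-health-risk assessment for
rivers affected by metal(loid) contamination — built around a dry-season
survey of a tropical river system draining a legacy copper mine, whose
site-by-analyte concentration table ships as the package's canonical
dataset.

The package is aimed at environmental geochemists and water-resource
analysts who have a table of filtered (< 0.45 µm) dissolved
concentrations (µg/L, with `"<x"` marks for values below detection) and
want the standard assessment chain computed reproducibly:

- **Regulatory-compliance indices** — Heavy metal Evaluation Index
  (HEI = Σ Cᵢ/MPLᵢ), weighted Water Quality Index
  (WQI = Σ Cᵢ·Wᵢ/(Sᵢ·ΣW) × 100), and the CCME WQI
  (100 − √(F1² + F2² + F3²)/1.732 from the scope, frequency and
  amplitude of objective excursions).
- **Baseline-deviation indices** — contamination factors CFᵢ = Cᵢ/Cbᵢ
  against a background derived from uncontaminated reference sites, and
  the Pollution Load Index PLI = ⁿ√(ΠCFᵢ).
- **Hakanson ecological risk** — Erᵢ = Trᵢ × CFᵢ on mean concentrations
  and their sum PERI, with the standard classification bands.
- **US-EPA health risk** — chronic daily dose (ingestion) and dermally
  absorbed dose, hazard quotients/index, and excess lifetime cancer risk
  for child and adult cohorts.
- **Source apportionment** — KMO and Bartlett diagnostics, varimax-rotated
  PCA with eigenvalue-1 retention, and average-linkage hierarchical
  clustering of sites and analytes with (D_link/D_max)×100 heights.
- **Synthetic river profiles** — a seedable generator (background ×
  point-source multipliers with exponential downstream attenuation,
  lognormal noise, detection-limit censoring) with known ground truth for
  end-to-end verification.

Left-censored values are never imputed silently: every pipeline entry
point requires an explicit substitution policy (`half_dl`, `zero`, `dl`,
`drop`), with half the detection limit as the conventional default.

## Worked example

```python
import pemriver as pr

samples   = pr.builtin_fixture()                      # 19-site survey, raw "<x" marks
resolved  = pr.resolve_censored(samples, "half_dl")
background = pr.derive_background(resolved, ("NY-01", "NY-13"))
river     = pr.subset(resolved, {"main_stem"})

print(pr.hei(river.get("NY-07")).value)               # 17.30  (low: HEI <= 40)
print(pr.pli(river.get("NY-05"), background).value)   # 14.51  (extreme: PLI >= 5)
report, parts = pr.ccme_wqi(river)
print(report.value, report.classification)            # 72.91 fair
eco = pr.ecological_risk(pr.mean_profile(river), background)
print(eco.peri, eco.peri_class)                       # 52963  extremely high
```

Or from the shell (`fixture` stands for the packaged dataset; any
CSV/TSV in the same layout works):

```text
$ pemriver indices --in fixture --out table3.csv
         distance_km    HEI    PLI     WQI
site_id
NY-01           0.00   0.85   0.91   17.39
NY-04           2.66  14.64  13.29  152.52
NY-05           2.82  15.19  14.51  159.10
NY-07           3.56  17.30  13.86  181.94
NY-08           4.25   5.84   8.17   66.97
NY-11           6.70   6.74   9.71   76.12
NY-12          10.39   5.88   9.25   67.95
NY-14          11.64   5.49   9.14   64.14
NY-15          16.20   4.66   8.71   55.75
CCME WQI = 72.9 (fair); F1=27.27 F2=22.22 F3=31.05
```

Reading the numbers: HEI stays below 40 everywhere, so the river is
compliant with potable-water limits overall ("low" contamination), yet
PLI exceeds 5 at every site downstream of the mine — concentrations sit
far above the upstream/confluence baseline ("extreme" deviation).  The
three sites inside the mining area (NY-04, NY-05, NY-07) fall in the
"poor" WQI band (100 ≤ WQI < 200); the catchment-level CCME WQI of 72.9
is "fair".  The ecological-risk table
(`pemriver ecorisk --in fixture --out eco.csv`) attributes the extreme
PERI almost entirely to cobalt and nickel.

Other subcommands: `pemriver load`, `healthrisk`, `sources`, `simulate`
(see `pemriver <cmd> --help`).

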