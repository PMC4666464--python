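# gillnetkit

Tools for quantifying a covert, unreported gillnet fishery and judging
whether it could overexploit its target stock — built for protected-area
fisheries where catch statistics do not exist and direct observation of
fishing is impossible.

The package chains three indirect lines of evidence:

1. **Derelict-gear shoreline surveys** — linear densities (items km⁻¹,
   g km⁻¹) of lost gillnet material along censused transects, mesh-size
   composition of net fragments, and between-year re-accumulation at
   cleared sites.
2. **Multi-mesh gillnet monitoring** — length-weight allometry
   (W = a·Lᵇ), panel- and set-level catch-per-unit-effort, the mesh size
   that maximises catch, and mixed-effects tests for year trends in
   abundance and body size with site random intercepts (likelihood-ratio
   p-values).
3. **Data-poor stock assessment** — von Bertalanffy growth
   L(t) = L∞(1 − e^(−K(t−t₀))); total mortality Z from a
   length-converted catch curve (Z = −slope of ln(count/Δt) against
   relative age over the trailing arm); natural mortality M from
   life-history invariants

       M = 4.899·t_max^−0.916        (longevity)
       M = 4.118·K^0.73·L∞^−0.33     (growth, L∞ in cm)
       M = 1.79·GSI                  (reproductive investment)

   fishing mortality F = Z − M; the proxy F_MSY = 0.87·M; maximum
   sustainable yield MSY = (1 − e^(−F_MSY))·B with B the hydroacoustic
   stock biomass; and effort scenarios translating MSY into net-nights,
   fishers, and the share of resident families that effort implies.

A synthetic-data module (`gillnetkit.synthio`) generates age-structured
populations, multi-mesh survey catches with mesh-selectivity and site
random effects, and Poisson debris fields, so every stage is testable end
to end without field data.

## Worked example

Three natural-mortality estimates feed the full harvest chain under the
default assessment inputs (Z = 0.42 yr⁻¹, 4.4 kg ha⁻¹ over 276,000 ha,
15 kg caught per night on 50 m of optimal-mesh net, 100 nights per
fisher-year, 5,440 residents in households of 3.6):

```python
import gillnetkit as g
from gillnetkit.harvest import assessment_report

inputs = g.AssessmentInputs()
table = g.assessment_table(
    {"hoenig_nls": 0.37, "pauly_nls_t": 0.27, "gunderson": 0.30}, inputs
)
print(assessment_report(table).to_string(index=False))
```

prints

```
     method    m    f  f_negative  f_msy   msy_kg  nights  fishers  percent_families  nights_per_family
 hoenig_nls 0.37 0.05       False   0.32 334239.0 22283.0    222.8              14.7               14.7
pauly_nls_t 0.27 0.15       False   0.23 254235.0 16949.0    169.5              11.2               11.2
  gunderson 0.30 0.12       False   0.26 278971.0 18598.0    186.0              12.3               12.3
```

Read the first row as: if natural mortality is 0.37 yr⁻¹, current fishing
mortality is only 0.05 yr⁻¹, but a fishery removing MSY ≈ 334 t yr⁻¹
(F_MSY = 0.32) would need about 22,300 net-nights — roughly 223 fishers
netting 100 nights a year, or 14.7% of resident families. Sustainable
yield could therefore be exceeded by a modest fraction of households, so
observed signs of widespread netting are a genuine conservation concern.
The `f_negative` flag marks scenarios where M exceeds Z (none here).

The same chain is available per component (`fmsy_from_m`,
`stock_biomass`, `msy`, `effort_requirements`), the catch-curve and
growth fits live in `gillnetkit.mortality`, and a CLI front end exposes
`simulate`, `gear-survey`, `trends`, `assess` and `report` subcommands
(`gillnetkit --help`).

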