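# nlossrisk

Monthly, block-scale risk indexing of nitrogen loss to water for pastoral and
arable landscapes, built for farm advisers, catchment scientists and
agri-environmental modellers who need a *relative* risk screen — not an
absolute loss estimate — that responds to soil, climate, slope, management and
mitigation.

## The model

Risk is the product of **source** and **transport**, scored per block (a group
of fields under similar management) and calendar month, for two flow paths:

```
Leaching index(m) = leach(m) × (urine + dung + effluent + fert + bg_residues + cultivation)
Runoff  index(m) = runoff(m) × (erosion + dung + fert + ag_residues)
```

where all sources are kg N ha⁻¹ month⁻¹ and `leach(m)`, `runoff(m)` are
dimensionless transport fractions in [0, 1]. Urine is washed into the soil and
excluded from runoff; eroded soil N and surface residues are excluded from
leaching.

Transport fractions come from a built-in daily water-balance surrogate (layered
tipping bucket with a conservative N tracer): 450 kg N ha⁻¹ is applied on the
15th of each month, the fraction passing 1000 mm depth within 730 days is the
leaching fraction, and surface runoff summed over the 30 days after application
and divided by 200 mm (capped at 1) is the runoff fraction.

Mitigation enters two ways: **source deltas** scale a source input by (1 + δ)
and the baseline is recomputed; **modifiers** (wetlands, denitrification beds,
…) multiply a pathway score by (1 − effectiveness), applied in series from most
to least effective, so a 20 %-then-10 % chain takes 100 → 80 → 72.

Validation converts risks and observed losses to ranks (1 = greatest, average
ranks for ties) and fits OLS with 95 % confidence and prediction bands; a
sensitivity analysis rescales each source to 50 %/150 % of baseline, and a
scale-factor diagnosis detects systematically attenuated land-use cohorts
(e.g. shallow-rooted vegetable crops) by comparing risk-vs-loss slopes.

## Worked example

Everything runs from synthetic fixtures — no downloads:

```bash
nlossrisk fixtures --seed 1 --n-blocks 4 --years 3 --out demo/scenario
nlossrisk transport-table --scenario demo/scenario --out demo/transport.csv
nlossrisk score --scenario demo/scenario --transport demo/transport.csv --out demo/report
```

which prints, among other rows:

```
$ head -3 demo/transport.csv
location_id,soil_id,slope,irrigated,month,leach_risk,runoff_risk
stony_shallow|cell_wet|flat|1,stony_shallow,flat,True,1,0.9999632309,0.01592105219
stony_shallow|cell_wet|flat|1,stony_shallow,flat,True,2,0.9999618731,0.00946389873

$ head -3 demo/report/risk_scores.csv
block_id,month,leach_index,runoff_index,total
B001,1,35.27870279,0.1783157845,35.45701857
B001,2,35.27865488,0.1059956658,35.38465055

$ cat demo/report/summary.txt
pathway shares: leaching=0.9826 runoff=0.0174
```

Read: block B001 (irrigated dairy on a stony, shallow, freely draining soil in
the wetter climate cell) has a January leaching transport fraction near 1 — on
that soil virtually all of a conservative tracer passes 1 m within two years —
so its January leaching index is ≈ 0.9999 × 35.3 kg N ha⁻¹ of leachable
sources ≈ 35.3. Runoff contributes under 2 % of this farm's total risk; the
scores are unitless ranks of relative risk, not kg N lost.

In Python, the modifier chain from the worked example above:

```python
>>> from nlossrisk import RiskScore, Modifier, BlockContext, apply_modifiers
>>> base = RiskScore("b", 1, leach_index=0.0, runoff_index=100.0)
>>> mods = [Modifier("constructed_wetland", "runoff", 0.1),
...         Modifier("natural_wetland", "runoff", 0.2)]
>>> final, trail = apply_modifiers(base, mods, BlockContext("dairy"))
>>> [s.runoff_index_after for s in trail], final.runoff_index
([80.0, 72.0], 72.0)
```

Other stages: `nlossrisk mitigate` (YAML plan of deltas + modifiers, emits an
audit trail CSV), `nlossrisk validate` (rank regression + plot),
`nlossrisk sensitivity`, `nlossrisk make-observations`.

## Layout

- `nlossrisk.transport` — water-balance surrogate and transport-risk protocol
- `nlossrisk.sources` — monthly N source inputs
- `nlossrisk.index_engine` — risk indices and aggregation
- `nlossrisk.mitigation` — source deltas and modifier chains
- `nlossrisk.validation` — rank regression, sensitivity, scale factor
- `nlossrisk.synthetic` — seeded scenario/observation generators
- `nlossrisk.io`, `nlossrisk.cli` — CSV/GeoJSON I/O and the CLI

See `docs/methods.md` for the model description, parameter defaults and known
limitations.
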