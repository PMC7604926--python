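# permkit

Permeation kinetics of antineoplastic agents through medical gloves:
flow-cell analysis, Fickian time-lag simulation, rank statistics, and
MW/LogP permeation-risk zoning.

Healthcare workers who prepare or administer cytotoxic drugs rely on
medical gloves as their primary barrier. Glove permeation is measured
in a continuous-flow in-line cell: a glove membrane separates a drug
*test solution* from a flowing receptor stream, the receptor is
collected over timed windows (0–15, 15–30, 30–60, 60–120, 120–240 min),
and the drug concentration of each collected fraction is assayed.
`permkit` implements the full analysis of such experiments and a
physics-based synthetic-data generator, so the statistical pipeline can
be developed and validated without laboratory data.

## What it computes

* **Permeation rate (PR)** per collection window (ng/min/cm²):
  `PR = (C × V) / t / S`, where `C` is the receptor concentration,
  `V` the collected volume, `t` the window duration and `S` the exposed
  membrane area. For a flow cell (`V = flow × t`) this is the
  interval-average rate `C × flow / S`.
* **Apparent permeation clearance** (µL/min/cm²):
  `CLp = 10⁻³ × PR₂₄₀ / C_test`, the final-window (120–240 min) rate
  normalized by the test-solution concentration (mg/mL). Drugs whose
  final window is entirely below the assay quantitation limit are
  reported as `CLp = 0` (censored).
* **Censoring**: an assay LOQ (ng/mL) converts to a PR-equivalent
  quantitation limit of `LOQ / 60` ng/min/cm²; readings below it enter
  replicate means as 0, and a timepoint is censored only when all of
  its replicates are below the limit.
* **Breakthrough detection**: earliest window whose mean PR strictly
  exceeds the 10 ng/min/cm² protective-glove limit.
* **Zone classification**: Zone A (LogP ≥ −1, MW ≤ 500 g/mol — high
  risk), Zone B (LogP ≥ −1, MW > 500 — moderate), Zone C (LogP < −1 —
  low), with configurable cutoffs and an `on_boundary` flag.
* **Spearman rank correlation**, tie-corrected (Pearson on midranks),
  with exact-enumeration or seeded Monte-Carlo permutation p-values —
  implemented from scratch because the clearance data contain tied
  censored zeros, where shortcut formulas are biased.
* **Membrane simulator**: Fickian time-lag diffusion with surface
  partitioning, mapped from (MW, LogP) by a frozen log-linear
  calibration, plus least-squares recovery of (D, K) from interval
  data. See [docs/methods.md](docs/methods.md) for the model, its
  numerics, and its known limitations.

## Worked example

```python
>>> import permkit as pk

# PR-equivalent quantitation limits from assay LOQs
>>> pk.loq_to_pr_limit(0.06)    # cyclophosphamide, 0.06 ng/mL
0.001
>>> pk.loq_to_pr_limit(0.03)    # ifosfamide
0.0005
>>> pk.loq_to_pr_limit(150)     # carmustine
2.5

# apparent clearance of fluorouracil: PR240 = 1140 ng/min/cm2 at
# C_test = 50 mg/mL
>>> pk.compute_clp(1140, 50, censored=False).clp_app
0.0228

# zone classification of the packaged ten-drug panel
>>> panel = pk.default_drug_panel()
>>> {a.drug: a.zone for a in pk.classify_panel(panel)}["Fluorouracil"]
'A'
```

Classifying the packaged panel yields Zone A = {carboplatin,
carmustine, cyclophosphamide, fluorouracil, ifosfamide}, Zone B =
{doxorubicin, etoposide, paclitaxel}, Zone C = {cisplatin,
oxaliplatin}; fluorouracil (LogP −1.0) sits exactly on the Zone A/C
boundary and is flagged.

## Command line

```bash
permkit simulate --seed 17 --out results/run17     # simulate + analyze
permkit analyze  --measurements m.csv --out out/   # analyze measured data
permkit classify                                   # zone table
permkit correlate --clearances out/clearances.csv --method mc
permkit report   --results results/run17           # summary
```

`simulate` writes `profiles.csv`, `clearances.csv`, `zones.csv`,
`correlations.csv`, `concordance.csv`, `measurements.csv` and
`run_metadata.json`. Output is a pure function of the configuration and
seed: reruns are byte-identical, and re-analyzing the exported
`measurements.csv` reproduces the bundle exactly.

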