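# netdea

Network slack-based Data Envelopment Analysis (DEA) with weakly disposable
undesirable outputs, built for hospital benchmarking where efficiency,
quality of care, and access to care have to be scored together.

## The problem

A hospital turns inputs (beds, clinical staff hours, operating costs) into
production volumes (inpatients, outpatient visits, surgeries) and, through
them, into outcomes — some desirable (patients not readmitted, timely hip
fracture surgery), some undesirable (pressure ulcers, post-operative sepsis,
delayed first appointments).  Classical DEA collapses all of this into one
black box, so a hospital can look efficient while delivering poor or
inaccessible care.  `netdea` instead models each decision-making unit (DMU)
as a **network of divisions** connected by intermediate products (links) and
scores each division with a **slack-based measure (SBM)**, a non-radial
efficiency score that does not force inputs or outputs to contract
proportionally.

## The model

DMU *o* consists of divisions k = 1, …, K.  Division k consumes external
inputs x_o^k, produces desirable outputs v_o^k and undesirable outputs
u_o^k, and exchanges link quantities z_o^(k,h) with other divisions.
Undesirable outputs obey **weak disposability**: a benchmark may scale a
peer's desirable and undesirable outputs down *jointly* by an abatement
factor θ_j ∈ [0, 1], but cannot discard the undesirable ones for free.
Splitting the intensity vector λ = μ + φ with θ_j = φ_j/(φ_j + μ_j)
linearises this, giving one LP per (DMU, division):

```
x_o^k = X^k (μ^k + φ^k) + s^k−                inputs
v_o^k = V^k φ^k − s^k+                        desirable outputs
u_o^k = U^k φ^k                               undesirable outputs
Z^(k,h) (μ^h + φ^h) = Z^(k,h) (μ^k + φ^k)     link ties, all pairs
Σ_j (μ_j^k + φ_j^k) = 1  per division         VRS only (dropped for CRS)
μ, φ, s^−, s^+ ≥ 0
```

The focused division's objective maximises its mean relative slack:
input-oriented divisions score `1 − (1/m_k) Σ_i s_i^−/x_io`, output-oriented
ones `1 / (1 + (1/r_k) Σ_r s_r^+/v_ro)`.  The overall score is the
arithmetic mean of the K divisional scores, so a DMU is efficient only if
every division is.  Scores are unit-invariant and lie in (0, 1]; the ratio
ρ_CRS/ρ_VRS is the scale efficiency.

Around the solver, the package provides the full benchmarking workflow:

* **screening** — Pearson correlation of variables over the pooled panel,
  clustering of same-role variables above a threshold (default 0.95), and
  sum-merging of clusters (e.g. doctor + nurse hours → clinical staff);
* **sensitivity** — enumerates every model variant that keeps one
  representative per correlation cluster and reports the per-DMU score
  spread across variants;
* **scenario** — best/worst-case counterfactuals for each quality/access
  variable (e.g. "no pressure ulcers" vs "every inpatient has one") and the
  per-DMU ratio of scenario to baseline score, aggregated by hospital group;
* **synthetic data** — a reproducible generator of hospital-like panels
  (27 DMUs × 4 periods × 19 variables E1–E9, Q1–Q7, A1–A3) so the entire
  pipeline runs without any external data.

Four network layouts are shipped (`modelA` … `modelD`): four-division
administration + inpatient/outpatient/surgical services, or three-division
efficiency/quality/access, each with headcount- or cost-based inputs.  They
are documented reconstructions and can be replaced by any YAML spec.

## Worked example

```python
import netdea as nd

panel = nd.generate_panel(nd.SyntheticConfig(seed=1))   # 27 hospitals, 2016-2019
spec = nd.read_model_spec("modelB")                      # efficiency/quality/access

vrs = nd.run_model(panel, spec, "vrs")
print(vrs.summary.head().round(3))
# H01    0.917
# H02    1.000
# H03    0.968
# H04    1.000
# H05    0.888
print(sorted(nd.classify_frontier(vrs.summary)))
# ['H02', 'H04', 'H10', 'H24']

clusters = nd.find_clusters(nd.pearson_matrix(panel), spec, 0.95)
print(clusters[0].variable_ids)      # ('E1', 'E2', 'E3', 'E4') — collinear inputs

impacts = nd.impact_analysis(panel, spec, nd.default_scenarios(["Q4"]),
                             "vrs", baseline=vrs)
for i in impacts:
    print(f"Q4 {i.mode}: mean impact {i.mean_impact:+.4f}")
# Q4 best: mean impact -0.0075
# Q4 worst: mean impact +0.0022
```

The summary is each hospital's overall VRS score averaged over the four
years; the four frontier hospitals have no feasible improvement in any
division.  The Q4 scenario replaces the pressure-ulcer column by its best
case (near zero) or worst case (every inpatient affected): here erasing
ulcers *lowers* mean measured efficiency by 0.75 % — the trade-off signal the
scenario analysis is designed to expose — while the worst case raises it
slightly.

The same workflow is available from the shell:

```bash
netdea simulate --seed 1 --out panel.csv
netdea run --panel panel.csv --model modelB --rts both --out scores.csv
netdea screen --panel panel.csv --model modelB --out clusters.json
netdea scenario --panel panel.csv --model modelB --out impacts.csv
```

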