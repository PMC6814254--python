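# coprescribenet

Network analysis of opioid doctor shopping from longitudinal prescription
claims. Doctor shopping — soliciting controlled substances from multiple
clinicians — is usually measured with crude prescriber-count thresholds.
This package implements a relational alternative: a **co-prescription
network** in which two patients are tied when they received opioids from
the same prescriber, with tie weight equal to the number of unique shared
prescribers. A patient's *prominence* in this network (weighted PageRank
percentile, with bipartite Co-HITS, standardized PageRank and logged
degree as alternates) is then related to quarterly opioid-risk outcomes in
random-intercept panel models.

The package is for epidemiologists and health-services researchers who
want to run or probe this kind of analysis on claims-shaped data. Real
claims are proprietary, so a seeded synthetic generator with planted
ground truth stands in for them: it reproduces the structural features the
analysis relies on (hub-heavy degree distributions, at-risk prescriber
clustering, rare outcomes) and makes every stage testable, including
parameter recovery of the panel models.

## The model

Per focal quarter *T*, non-MAT opioid fills pooled over {*T*−2, *T*−1, *T*}
define a bipartite patient–prescriber graph; its projection onto patients
has weights w_ij = |N(i) ∩ N(j)| (unique shared prescribers). Prominence is
weighted PageRank,

    PR(i) = (1 − d)/N + d · Σ_{j ∈ M(i)} w_ij · PR(j) / s_j ,   d = 0.85,

with each undirected edge treated as two directed edges, s_j the strength
of node j, and isolate (dangling) mass redistributed uniformly so that
Σ PR = 1. Scores are reported as within-quarter percentiles.

The percentile x_it is decomposed into between-person and within-person
terms, BP_i = mean_t(x_it)/10 and WP_it = (x_it − mean_t(x_it))/10, and
four outcomes per patient-quarter — opioid fill count, max daily MME > 90
mg, accidental overdose, opioid use disorder — are regressed on BP, WP and
controls (gender, age, insurance, cancer, unique-prescriber count, state
fixed effects) in random-intercept GLMMs: negative binomial for the count,
logit for the binaries, fitted by maximum likelihood with Gauss–Hermite
quadrature. Results are reported as IRRs/ORs with 95% CIs, the
random-intercept variance σ_u², latent-scale ICC, BIC, and
population-averaged predicted margins.

See `docs/methods.md` for the full account of models, defaults and
numerical choices.

## Worked example

The canonical tie-weight example — patients A and B each prescribed
opioids by the same three providers within the pooled window:

```python
import pandas as pd
from coprescribenet.network import (
    filter_opioid_claims, build_bipartite, project_patients,
)
from coprescribenet.centrality import pagerank

rx = pd.DataFrame(
    [{"patient_id": p, "prescriber_id": d, "quarter": q,
      "drug_code": "oxycodone", "daily_dose_mg": 10.0, "mme_factor": 1.5,
      "fill_day": 0, "days_supply": 30, "is_mat": 0}
     for p, d, q in [("A", "D1", 3), ("A", "D2", 4), ("A", "D3", 5),
                     ("B", "D1", 5), ("B", "D2", 5), ("B", "D3", 5)]]
)
cg = project_patients(build_bipartite(filter_opioid_claims(rx), 5))
print("tie weight A-B:", cg.graph["A"]["B"]["weight"])
print(pagerank(cg).round(4).to_dict())
```

prints

```
tie weight A-B: 3
{'A': 0.5, 'B': 0.5}
```

— the three shared prescribers give weight 3, and the symmetric two-node
graph splits the PageRank mass evenly.

End to end on synthetic data, with a fitted panel model:

```python
from coprescribenet.synth import SynthConfig, generate_study
from coprescribenet.network import filter_opioid_claims
from coprescribenet.centrality import centrality_table
from coprescribenet.outcomes import assemble_panel
from coprescribenet.panel_models import decompose, fit_glmm, icc

cfg = SynthConfig(n_patients=2000, n_prescribers=250, seed=1)
study = generate_study(cfg)                      # two-stage: claims, then
rx_f = filter_opioid_claims(study["rx"])         # outcomes planted on the
cent = centrality_table(rx_f, cfg.panel_quarters,  # realized network
                        max_quarter=cfg.n_quarters - 1)
panel = assemble_panel(study["patients"], study["rx"], study["dx"],
                       cent, cfg.panel_quarters)
res = fit_glmm(decompose(panel), outcome="oud",
               covariates=["female", "age_10yr", "cancer_dx"])
print(res.summary_frame().round(3))
print(f"sigma_u^2 = {res.sigma_u2:.3f}  ICC = {icc(res):.3f}")
```

prints (seed 1):

```
             coef     se     OR  ci_low  ci_high
const     -10.119  0.936  0.000   0.000    0.000
female     -0.240  0.303  0.787   0.435    1.424
age_10yr   -0.019  0.087  0.981   0.826    1.164
cancer_dx  -0.285  0.466  0.752   0.302    1.874
bp          0.691  0.081  1.995   1.703    2.336
wp         -0.088  0.102  0.916   0.751    1.118
sigma_u^2 = 2.748  ICC = 0.455
```

The between-person odds ratio per 10 PageRank percentile points is
estimated at 2.00 — the generator's planted OUD effect is exactly 2.0 —
while the small planted within-person effect (1.11) is inside its wide CI
at this desk-scale sample; the ICC says ~46% of latent outcome variance is
stable between-patient heterogeneity.

A `coprescribenet` CLI wraps the same stages
(`synth | network | centrality | outcomes | fit | run | validate`); `run`
executes the whole pipeline into a directory with a checksum manifest.

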