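# methtrio

**Is a mixed-tissue methylome the weighted sum of its parts?**

`methtrio` analyzes DNA methylation array studies with a *trio* design: each
subject contributes a buffy-coat sample (the whole leukocyte layer of a blood
draw) plus its two isolated constituent fractions — polymorphonuclear (PMN)
leukocytes and lymphocytes. Because the buffy coat is physically a mixture of
those fractions, its beta-value profile should be their weighted combination.
The package tests that premise probe by probe and characterizes where it
fails, which matters to anyone deciding whether whole buffy-coat methylation
profiles are a faithful surrogate for cell-type-resolved profiles, or whether
the cell-separation process itself perturbs methylation.

## What it computes

For subject *i* with beta vectors over probes, the unconstrained no-intercept
least-squares fit

&nbsp;&nbsp;&nbsp;&nbsp;β<sub>buffy,i</sub> ≈ w<sub>P,i</sub> · β<sub>PMN,i</sub> + w<sub>L,i</sub> · β<sub>lymph,i</sub>

recovers the subject's differential blood count (w sums just below 1 when the
mixture premise holds). Per probe *g* and subject *i*, the residual

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>gi</sub> = β<sub>buffy,gi</sub> − (w<sub>P,i</sub> β<sub>PMN,gi</sub> + w<sub>L,i</sub> β<sub>lymph,gi</sub>)

is pooled across all probe×subject trios, standardized, and flagged
*discordant* when |z| exceeds the two-sided Bonferroni normal cutoff at
family level α = 0.05 over the number of probes (z = 5.29 at 412,481 probes).
A probe is discordant if at least one of its trios is flagged; probes whose
residual falls below −0.6 form the extreme-negative *peak* — the signature of
isolated fractions that gained methylation in vitro while the pre-separation
buffy coat did not.

Around that core the package provides:

- **Differential methylation** (`PairedDMP`): within-subject paired
  comparisons (buffy−PMN, buffy−lymphocyte, PMN−lymphocyte) with
  empirical-Bayes moderated t-statistics
  (s̃² = (d₀s₀² + d·s²)/(d₀+d), df = d₀+d), Benjamini-Hochberg adjustment,
  and the |Δβ| > 0.1 effect filter — run before and after discordant-probe
  removal to ask whether discordance produced false positives.
- **Probe characterization**: mapping-uniqueness fractions, GC-content
  comparison, and per-region (CpG island / shore / shelf / open sea) 2×2
  chi-squared enrichment of discordant vs all probes.
- **QC**: detection-p-value call-rate filtering and beta-density summaries.
- **Synthetic cohorts** (`simulate_cohort`): trio cohorts with bimodal beta
  baselines, ~30% PMN/lymphocyte differences, known mixing weights, and
  injected open-sea-biased methylation-gain discordance — with full ground
  truth, so every stage is testable without external data.

## Worked example

```python
import methtrio as mt

cohort = mt.simulate_cohort(mt.SimulationConfig(seed=1))   # 29 subjects, 20k probes
results = mt.MixtureModel(cohort.beta, cohort.design).fit()
print(results.weights.head(3))
#             w_pmn  w_lymph  coefficient_sum  residual_sd  n_probes_used
# subject_id
# S01        0.7199   0.2610           0.9808       0.0833          20000
# S02        0.6347   0.3461           0.9808       0.0825          20000
# S03        0.6118   0.3691           0.9809       0.0823          20000

partition = mt.standardize_and_flag(results.residuals())
print(partition.counts())
# {'n_discordant_trios': 5800, 'pct_discordant_trios': 1.0,
#  'n_discordant_probes': 200, 'n_peak_probes': 199, ...}

enrich = mt.region_proportion_tests(
    partition.discordant_probes, cohort.beta.probe_ids, cohort.annotation
)
print(enrich.table[["prop_group", "prop_reference", "pvalue", "direction"]])
#               prop_group  prop_reference     pvalue direction
# island             0.125          0.3105  1.585e-08     under
# open_sea           0.595          0.3569  2.881e-12      over
```

Reading the output: the fitted weights recover each subject's PMN/lymphocyte
blood count (sums ≈ 0.98 — slightly below 1 because the 200 injected
discordant probes violate the mixture premise); all 200 injected probes are
flagged, every flagged trio has a negative residual, and the discordant set
is significantly depleted of CpG islands and enriched for open-sea probes —
the package's positive control for the characterization stage.

The same pipeline runs from the shell:

```bash
methtrio simulate --out sim/
methtrio run --config cfg.yaml --out results/
```

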