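# vusnet

Network-based scoring of variants of unknown significance (VUS) for
case-control cohorts.

Univariate odds-ratio analysis leaves a grey zone: variants individually
too weak to pass a threshold, yet informative when acting in synergy.
`vusnet` scores each candidate variant by placing its gene on
evidence-typed gene–gene networks (physical interaction, genetic
interaction, shared pathway, co-expression, co-localization), pooling all
dataset variants in the two-hop subnetwork around it, and fitting two
polygenic risk models on the 0/1/2 allele-dosage matrix:

- **Model 1** — ridge-penalized logistic regression on the whole pool;
- **Model 2** — the same pool *without* the candidate.

The models are compared by the Integrated Discrimination Improvement

```
IDI = slope(Model 1) − slope(Model 2),    slope = E[risk | case] − E[risk | control]
```

with the asymptotic paired standard error, a two-sided p-value,
continuous NRI and both ROC AUCs (paired AUCs compared by DeLong's
test).  A variant with IDI ≥ +0.02 is called **pro-disease**, ≤ −0.02
**protective**, otherwise unclassified.  Selected variants are then added
to the odds-ratio baseline and the gain in leave-one-out cross-validated
AUC is measured against a 200-iteration random-addition control.  A
guilt-by-association path classifies an unknown gene by majority vote of
its top-2 labelled network neighbours.

The package also ships a synthetic-data generator (Hardy–Weinberg
genotypes, additive logistic disease model with planted network modules,
per-sample frequency-matched mock variants, knowledge-base fixtures) so
that every stage is testable without any external cohort.  See
`docs/methods.md` for the model, the numerical choices and the
generator's scope.

## Worked example

Score a simulated cohort in which one five-gene module (two variants per
gene, per-allele log-odds 0.8) drives disease among null background
variants and 20 frequency-matched mocks:

```python
import vusnet as vn

groups = (vn.VariantGroup(genes=("MA", "MB", "MC", "MD", "ME"),
                          variants_per_gene=2, beta=0.8, maf=0.3),)
spec = vn.SimulationSpec(n_cases=150, n_controls=150, groups=groups,
                         n_noise_variants=20, seed=21)
g, y, truth = vn.simulate_cohort(spec)
g, mocks = vn.impute_mock_variants(g, 20, seed=22)
nets = vn.simulate_networks(truth, seed=23)

results = vn.VariantScoringModel(g, y, nets).fit()
print(results.summary())
```

```
Variant scoring results
=========================================================
variants scored:        50
risk models evaluated:  81
unique genes:           15
pro-disease (IDI >= +0.02): 10
protective  (IDI <= -0.02): 0
unclassified:           37
skipped (gene off-network): 3
---------------------------------------------------------
top 10 by |IDI|:
variant_id  gene evidence_types  n_subnetwork_genes  n_model_variants   auc1   auc2     idi  idi_se     idi_p    nri  vus_coef_p classification
   var0009    ME       physical                   5                16 0.8063 0.7752 0.05875 0.01407 2.966e-05 0.3733   1.887e-05    pro_disease
   var0010    ME       physical                   5                16 0.8063 0.7775 0.05271 0.01317 6.318e-05   0.52   3.683e-05    pro_disease
   var0007    MD       physical                   5                16 0.8063 0.7816  0.0439 0.01268 0.0005367   0.44   7.861e-05    pro_disease
   ...
```

Reading the output: the planted module's ten variants fill the
pro-disease calls — for the top variant, the 16-variant subnetwork model
(`auc1` 0.806 on leave-one-out risks) loses 0.059 of discrimination
slope when that single variant is removed (`auc2` 0.775, IDI 0.059,
p ≈ 3e-5).  Mocks and background variants cluster inside the ±0.02 band
(37 unclassified; one mock false positive in this draw), and three
variants sit on genes absent from every network.

The same pipeline is available from the shell:

```
vusnet simulate --n-mock 150 --seed 0 --out fixtures/
vusnet score --genotypes fixtures/genotypes.tsv --phenotypes fixtures/phenotypes.tsv \
    --network physical=fixtures/network_physical.tsv ... --seed 0 --out run/
vusnet baseline ... / vusnet improve ... / vusnet classify-gene ... / vusnet report ...
```

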