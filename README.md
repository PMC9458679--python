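# mefv-origins

Familial Mediterranean fever (FMF) is an autosomal recessive disease driven
largely by a handful of founder variants in the *MEFV* gene (M694V, V726A,
E148Q, M680I, M694I). In a referral population with diverse diaspora
ancestry, most patients do not have a single country of origin, so the
classical question — *which variant is typical of which origin?* — cannot be
answered by simple per-country frequency tables.

`mefv-origins` implements the machine-learning pipeline that answers it for
mixed-ancestry cohorts, for geneticists and epidemiologists working with
carrier-ascertained referral data:

1. **Origin score.** Each referral's four grandparent origins are encoded as
   ancestry fractions: a grandparent from country *c* contributes 0.25 to
   feature *x_c*, so a subject with two Algerian grandparents, one Moroccan
   and one Iraqi has *x* = (Algeria 0.5, Morocco 0.25, Iraq 0.25). If one
   grandparent on a parental side is unknown, it is imputed from the other;
   subjects with a fully unknown side are excluded. Countries with fewer
   than 15 supporting referrals are dropped from the feature set.
2. **Per-variant logistic models.** For each common variant *v*, a binary
   logistic regression (fitted in-package by Newton/IRLS, ridge penalty
   λ = 1 by default) predicts carriage of *v* from the country fractions
   plus sex:  P(y=1|x) = σ(β₀ + βᵀx). The modeling subset keeps only
   single-variant-type carriers (heterozygous or homozygous for M694V,
   V726A or E148Q); compound heterozygotes are excluded.
3. **Evaluation and ranking.** Tenfold cross-validation and a
   1000-replicate out-of-bag bootstrap score the model by AUC; coefficient
   vectors are averaged across resamples and countries ranked by mean
   coefficient, giving the most and least associated origins per variant.
4. **Group-of-four dose analysis.** The four top- and bottom-ranked
   countries form groups; referrals are binned by *grandparent dose* (the
   fraction of grandparents from the group: 0, 0.25, …, 1) and carrier
   prevalence is tabulated per dose level.

A synthetic-cohort generator (`mefv_origins.synthetic_cohort`) produces
carrier-ascertained cohorts with known per-country allele frequencies,
endogamy/admixture structure and missing grandparent data, for calibration
and recovery testing. The published genotype-prevalence table of 1781
referrals ships as a packaged fixture (`mefv_origins.datasets`).

## Worked example

Simulate a planted-cluster cohort and run the M694V association end to end:

```sh
mefv-origins simulate --preset paper-like --seed 42 --retained 1800 \
    --out cohort.tsv --truth truth.yaml
mefv-origins associate cohort.tsv --variant M694V --scheme kfold \
    --seed 42 --out-dir run_m694v
```

which prints

```
wrote 1800 referrals to cohort.tsv
M694V: mean AUC 0.841 over 10 resamples (0 skipped); top ('Morocco',
'Algeria', 'Libya', 'Tunisia'), bottom ('Romania', 'Iran', 'Poland', 'Yemen')
```

The generator planted a high M694V allele frequency (0.25) in exactly
Morocco, Algeria, Libya and Tunisia; the ranking recovers that set, with a
cross-validated AUC of 0.84. `run_m694v/` then contains the full bundle —
genotype summary, origin matrix, per-resample coefficients, ranking, and
the dose tables, e.g. `dose_top.tsv`:

```
dose    carriers  non_carriers  total  prevalence
0.0     217       829           1046   0.207
0.25    47        27            74     0.635
0.5     236       71            307    0.769
0.75    11        4             15     0.733
1.0     280       38            318    0.881
```

Carrier prevalence climbs from 21% among referrals with no grandparent from
the top group to 88% among those with all four — the dose-response signature
of a founder variant.

The packaged referral table reproduces the published prevalence statistics:

```sh
python - <<'EOF'
from mefv_origins.datasets import table1_cohort
from mefv_origins import prevalence
c = table1_cohort()
p = prevalence(c, "M694V")
print(len(c), p.count, f"{p.percent:.1f}%")   # 1781 1286 72.2%
EOF
```

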