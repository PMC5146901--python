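# rhythmoscope

Daily-rhythmicity analysis of qPCR gene-expression time series, built
for circadian studies of the kind run on fish skeletal muscle: animals
sampled every 3 h across one light–dark cycle (Zeitgeber times ZT0,
3, …, 24; n = 6 per timepoint), clock-gene and myogenic-gene panels
assayed by quantitative real-time PCR, and rhythmicity read off a
fixed-period cosinor fit.

The package implements the full analysis chain:

- **Relative quantification** by R = 2^−ΔΔCt with
  ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator,
  the reference Ct being the arithmetic mean over the reference-gene set.
- **Reference-gene selection** by geNorm: stability
  M_j = mean_k SD_samples(log2 q_j/q_k), iterative worst-first exclusion,
  and the pairwise variation V(n/n+1) between normalisation factors.
- **Single-cosinor rhythmometry** at a fixed 24-h period:
  f(t) = M + A·cos(πt/12 − φ) fitted by ordinary least squares on
  {1, cos(πt/12), sin(πt/12)}, with A = √(β²+γ²), φ = atan2(γ, β), and
  the peak at ZT = 12φ/π hours. A gene is called rhythmic when the
  amplitude noise/signal statistic P = SE(A)/A is strictly below 0.3,
  with SE(A) from the delta method on the OLS coefficient covariance.
- **Per-timepoint comparisons** by one-way ANOVA and Duncan's multiple
  range test, rendered as compact letter displays.
- **Rhythm-gated correlation screening**: Pearson r between per-timepoint
  mean profiles, keeping pairs with |r| > 0.5 and at least one rhythmic
  member; 0.5 < |r| < 0.80 is moderate, |r| ≥ 0.80 strong.
- **A seeded synthetic qPCR generator** reproducing the study design
  (9 ZTs × 6 replicates, 26 target genes per tissue with published
  cosinor parameters, 6 candidate reference genes including a drifting
  one), so the whole chain is testable without any external data.

Core fitting steps are exposed as scikit-learn style estimators
(`CosinorRegressor`, `DeltaDeltaCt`, `GeNormSelector`) with plain
functions (`fit_cosinor`, `delta_delta_ct`, `genorm`, `duncan_letters`,
`correlation_table`) as thin wrappers.

## Worked example

```python
from rhythmoscope import RunConfig, run_pipeline

result = run_pipeline(RunConfig(tissue="fast", seed=1, outdir="results/fast"))
print("references:", result["references"])
print("geNorm ranking:", result["genorm"].ranking)
row = result["rhythm"].set_index("gene").loc["arntl1"]
print(f"arntl1: A={row.amplitude:.3f}, P={row.p_value:.3f}, "
      f"peak ZT={row.zt_h:.2f}, rhythmic={row.rhythmic}")
```

prints

```
references: ['rpl13']
geNorm ranking: ['rpl13', 'actb', 'rps29', 'hprt1', 'gapdh', 'rna18s']
arntl1: A=0.839, P=0.025, peak ZT=10.49, rhythmic=True
```

The simulated fast-muscle dataset is normalised against the most stable
reference candidate (rpl13, as geNorm ranks the drifting 18S rRNA last),
and the cosinor fit for *arntl1* recovers the generating peak time
(ZT ≈ 10.5 h, mid-light phase) with an amplitude noise/signal ratio
P = 0.025 < 0.3, i.e. clear daily rhythmicity. Note the amplitude is on
the 2^−ΔΔCt scale, which is defined only up to the calibrator constant;
P, the acrophase and the rhythmic flag are scale-free.

The same stages are available from a shell:

```sh
rhythmoscope run --tissue fast --seed 1 --out results/fast
rhythmoscope simulate --tissue slow --seed 7 --out ct.csv
rhythmoscope quantify ct.csv --target-genes per1,per2 \
    --reference-genes rpl13,actb,hprt1 --genorm --out expr.csv
rhythmoscope rhythm expr.csv --threshold 0.3 --out rhythm.csv
```

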