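# p53decode

Tools for studying how the *temporal pattern* of a transcription factor is
decoded into the dynamics of its target mRNAs and proteins, built around the
p53 system: after γ-irradiation p53 levels **oscillate** (~5.5 h period),
while irradiation plus an MDM2 inhibitor produces continuously **rising**
p53. Targets read these two inputs very differently — some proteins follow
the pulses, some accumulate, and some are induced under exactly one regime —
and the package implements the quantitative machinery for dissecting why:

- a **discrete-time kinetic model** with translational delay,

  ```
  mRNA(t) = (1 − kd_mRNA)·mRNA(t−1) + kp_mRNA·p53(t−1)
  prot(t) = (1 − kd_prot)·prot(t−1) + kp_prot·mRNA(t − tdel)
  ```

  fitted per gene (degradation constants and delay from trajectory shape,
  production constants by least-squares scaling, R² reported as fit
  quality), with cross-condition prediction: parameters fitted under
  oscillatory p53 predict the trajectory under rising p53;
- **differential-expression filters** (fold change > 1.5 for mRNA / > 1.15
  for protein at any time point in 1–9 h, Benjamini–Hochberg FDR, replicate
  Pearson correlation, and an early between-condition area filter for
  proteins);
- **fuzzy c-means clustering** of z-scored time courses (fuzzifier 1.3;
  five mRNA clusters, three protein clusters) with induced/repressed
  direction labeling;
- a **dynamical category table**: each gene's (mRNA class × protein class)
  pair maps to a letter a–k, annotated with the decoding mechanism that can
  produce it (degradation-rate tuning, activation thresholds, coherent and
  incoherent feed-forward loops);
- **network-motif simulators** for those mechanisms, demonstrating
  persistence detection (cFFLs induce only under sustained input) and
  mRNA/protein inversion (iFFLs silence the protein precisely when the mRNA
  is highest);
- the **diff / diff_early statistics**, summed pointwise relative
  differences between the basal-normalized protein trajectories of the two
  conditions over 3–9 h and 0–3 h, plus a functional-class (antiproliferative
  vs other) comparison of 24 h fold changes;
- a **synthetic-data generator** that reproduces the study design — two
  conditions, two replicates, hourly sampling 0–9 h plus 24 h, log-normal
  measurement noise — with ground-truth mechanism labels, so the whole
  pipeline is testable end to end.

## Worked example

```python
import numpy as np
from p53decode import TimeGrid, OSCILLATORY, RISING
from p53decode.synthetic import (OSC_P53_SPEC, RISING_P53_SPEC, archetype,
                                 hourly_p53, NoiseModel, simulate_gene)
from p53decode.kinetic_model import fit_mrna, fit_protein, predict_protein, sample_at

grid = TimeGrid()                      # 0..9 h hourly + 24 h
p53_osc = hourly_p53(OSC_P53_SPEC)     # oscillatory input, 5.5 h period
p53_rise = hourly_p53(RISING_P53_SPEC)

# an MDM2-like target: fast mRNA and protein turnover, two noisy replicates
gene = simulate_gene(archetype("a"), p53_osc, p53_rise,
                     NoiseModel(cv=0.05), n_replicates=2,
                     rng=np.random.default_rng(42), gene_id="MDM2_like", grid=grid)

mrna_obs = gene.replicate_mean("mRNA", OSCILLATORY)
prot_obs = gene.replicate_mean("protein", OSCILLATORY)

fit_m = fit_mrna(sample_at(p53_osc, grid), mrna_obs)
fit_p = fit_protein(mrna_obs, prot_obs)
print(f"mRNA fit:    kd_mrna = {fit_m.params.kd_mrna:.2f}  R2 = {fit_m.r2:.2f}")
print(f"protein fit: kd_prot = {fit_p.params.kd_prot:.2f}  "
      f"tdel = {fit_p.params.tdel:.2f} h  R2 = {fit_p.r2:.2f}")

_, r2_pred = predict_protein(fit_p.params,
                             gene.replicate_mean("mRNA", RISING),
                             gene.replicate_mean("protein", RISING))
print(f"cross-condition prediction (rising): R2 = {r2_pred:.2f}")
```

prints

```
mRNA fit:    kd_mrna = 0.98  R2 = 0.99
protein fit: kd_prot = 0.83  tdel = 0.50 h  R2 = 0.99
cross-condition prediction (rising): R2 = 1.00
```

The gene was generated with `kd_mrna = kd_prot = 0.9` and `tdel = 0.5 h`:
both degradation constants and the delay come back close to truth from two
noisy replicates, the fit R² is near 1, and — because the same parameters
govern both conditions for a simply regulated gene — the oscillatory-fitted
parameters predict the rising-condition protein almost perfectly. For a gene
wired through a post-transcriptional coherent FFL the same procedure fails
(prediction R² well below 0.5), which is exactly the signature the category
analysis uses to flag decoding mechanisms beyond simple regulation.

The full pipeline runs from a shell:

```bash
p53decode run --seed 1 --outdir out          # simulate → filter → cluster →
                                             # fit → predict → classify → compare
p53decode motif HSPG2-like                   # iFFL preset under both regimes
```

`out/` then contains one delimited table per stage (`de_summary.csv`,
`clusters.csv`, `fits.csv`, `predictions.csv`, `categories.csv`,
`diff_stats.csv`) plus a `manifest.json` recording the seed, config hash and
per-stage counts.

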