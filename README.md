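# wgdctdna

Tools for asking a liquid-biopsy question: does tumor **whole-genome
doubling (WGD)** — a mitotic event that leaves every cancer cell with twice
the DNA — make **circulating tumor DNA (ctDNA)** easier to detect in plasma?
The package is aimed at cancer-genomics analysts working with
allele-specific copy-number profiles of colorectal tumors and
tumor-informed plasma sequencing.

It provides, as importable modules and a small CLI:

* **WGD classification** from segmented allele-specific copy numbers, by two
  rules: the major-copy-number rule (WGD+ iff the fraction of the covered
  genome with major allele copy number ≥ 2 exceeds 0.5) and the orthogonal
  LOH rule (WGD+ iff cancer-cell ploidy ψ > 2.5 − 1.25·FracLOH, where
  FracLOH is the genome fraction with minor copy number 0);
* **clonality filtering** via the standard purity/copy-number correction
  CCF = VAF·(ρ·CN + 2(1−ρ)) / (ρ·m), with mutations of CCF < 0.9 treated as
  subclonal, and panel-overlap routing to ddPCR vs deep sequencing;
* a **ctDNA positivity caller**: per-strand beta-binomial background models
  fitted from a panel of normal cfDNA samples, exact tail tests with
  strand-AND combination, and the any-site rule (positive iff some tracked
  mutation has combined statistic < 0.05);
* **association statistics**: 2×2 odds ratios OR = ad/bc with Wald or
  profile-likelihood intervals, stratified tables, Cohen's kappa, and
  multivariable logistic regression;
* a **synthetic cohort generator** implementing an explicit mechanism —
  plasma tumor fraction scales with tumor size, stage and per-cell genome
  copies (ploidy/2), gated by the assay's limit of detection — so the whole
  pipeline is testable end to end without patient data.

## Worked example

```python
import numpy as np
from wgdctdna.cohort_sim import SimConfig, simulate_cohort
from wgdctdna.association import stratified_association

sim = simulate_cohort(SimConfig(n_patients=5000, seed=0))
print(f"positivity {sim.cohort['ctdna_detected'].mean():.1%}")
print(stratified_association(sim.cohort, "wgd", "ctdna_detected",
                             "uicc_stage")[["odds_ratio", "ci_low", "ci_high"]].round(2))
```

prints

```
positivity 64.0%
         odds_ratio  ci_low  ci_high
stratum
overall        1.49    1.33     1.68
I              2.18    1.68     2.82
II             1.44    1.21     1.72
III            1.17    0.94     1.46
```

Read: under the generator's mechanism, genome-doubled tumors have ~2.2-fold
higher odds of a positive plasma test in stage I, the advantage shrinks in
stage II, and in stage III — where shedding alone usually clears the limit
of detection — the interval covers the null. Disabling the per-cell DNA
effect (`SimConfig(ploidy_effect=False)`) flattens all odds ratios to ≈1.

The same analyses run from the shell:

```sh
wgdctdna simulate -n 1000 --seed 7 -o simulated/
wgdctdna wgd-call simulated/segments.tsv -o wgd_calls.tsv
wgdctdna concordance simulated/segments.tsv
wgdctdna associate simulated/cohort.csv -o association/
wgdctdna reproduce-published
```

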