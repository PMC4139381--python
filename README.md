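# devptn

Tools for classifying genes by their expression dynamics across ordered
developmental stages and for testing whether such developmentally
defined gene groups carry prognostic information for tumor cohorts.

The motivating biology: a tumor can be viewed as an organ undergoing
aberrant organogenesis, so genes whose expression falls steadily as the
normal organ matures may be reactivated in cancer — and their expression
level in a tumor may predict outcome. `devptn` implements the full
analysis chain for this idea on lung adenocarcinoma-style data:

1. **Pattern classification.** For four ordered stages (whole embryo →
   early lung → middle lung → mature lung) there are three adjacent
   transitions. Each is called per gene as `u` (higher in the earlier
   stage), `d` (higher in the later stage) or `n` (no significant
   change) from a two-sided unpaired t-test with a joint raw p < 0.05
   and Benjamini–Hochberg FDR q < 0.01 criterion. The three calls form
   a code over {u, d, n}, giving 3³ = 27 patterns (PTNs): `uuu`
   (steadily decreasing) is PTN1, the flat `nnn` is PTN14, and the rest
   are ordered by the Pearson correlation of their idealized stage
   template with the PTN1 template, placing `ddd` at PTN27. The 26
   non-flat patterns are the vPTNs.
2. **Tumor comparison.** Tumor-vs-mature differential genes (two-sided
   t-test, Bonferroni-adjusted p < 0.01) and their hypergeometric
   over-representation in each vPTN, with a Spearman trend statistic
   for the characteristic drift of tumor-upregulated genes toward
   low-numbered (development-decreasing) patterns.
3. **Signature permutation.** For each size n ∈ {3, 6, …, 21}, random
   n-gene signatures are drawn without replacement from a candidate
   list; each signature splits every patient cohort into two groups by
   k-means (k = 2) on the z-scored signature submatrix and is scored by
   the log-rank test. A signature is a *robust effective signature*
   only if p < 0.05 in **every** cohort simultaneously. The per-n
   robust fraction is compared against a fixed random baseline list of
   200 genes.
4. **Synthetic data.** Generators with planted ground truth — staged
   matrices with known pattern codes, tumor cohorts whose exponential
   survival times follow a proportional-hazards model driven by a
   latent score loaded on a planted prognostic gene set, probe maps and
   qPCR ΔCt tables — so every mechanism is testable end to end.

## Worked example

```python
from devptn import (SyntheticConfig, AnalysisThresholds, classify_genes,
                    generate_staged_expression, generate_tumor_cohorts,
                    make_random_baseline, permutation_run, compare_lists)

cfg = SyntheticConfig(master_seed=1)        # 1000 genes, stages 10/10/9/15
matrix, design, truth = generate_staged_expression(cfg)
assignment = classify_genes(matrix, design)
print(assignment["ptn_index"].value_counts().loc[[1, 14, 27]])

cohorts, truth = generate_tumor_cohorts(cfg, truth)  # 3 cohorts x 100 patients
th = AnalysisThresholds(reps=50, n_values=(12,))
planted = permutation_run(truth.prognostic_genes, cohorts, th, 1, list_label="planted")
baseline = permutation_run(make_random_baseline(matrix.gene_ids, 200, 1),
                           cohorts, th, 1, list_label="random")
print(compare_lists(planted, baseline)[["fraction_planted", "fraction_random"]])
```

Output:

```
ptn_index
1     100
14    799
27    100
Name: count, dtype: int64
    fraction_planted  fraction_random
n
12               1.0             0.08
```

The classifier recovers all 100 planted decreasing genes as PTN1 and
keeps 799 of the 800 flat genes in PTN14 (one false transition call at
these thresholds). Every 12-gene signature sampled from
the 50 planted prognostic genes separates survival in all three cohorts
(fraction 1.0), while random signatures rarely do; the baseline's 0.08
reflects the planted genes it picked up by chance from the full
universe.

A command-line interface mirrors the library:

```bash
devptn simulate --preset study-shape --seed 17 --out datadir/
devptn classify --expression datadir/developmental_expression.tsv \
    --design datadir/stage_design.tsv --out assignment.tsv
devptn permute --candidates ptn1.txt --cohorts cohorts.yaml \
    --n 3,6,9,12,15,18,21 --reps 10000 --seed 17 --out summary.tsv
devptn run-all --config config.yaml --out rundir/
```

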