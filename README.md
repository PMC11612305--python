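# parenclitic

Parenclitic deviation networks for DNA methylation arrays: classify tumour
samples as **aggressive** vs **non-aggressive** from genome-wide beta
values, and rank candidate CpG loci, in the "small n, big k" regime where
cohorts are tiny and loci number in the hundreds of thousands.

## The idea

A reference (non-aggressive) cohort defines what *normal* joint
methylation looks like: for every unordered pair of panel loci
(cg_i, cg_j) a bivariate Gaussian mixture with up to 4 components is
fitted to the reference points (β_i, β_j) — the components capture the
pair's joint methylation states (both methylated, both unmethylated, one
of each, intermediate). Any new sample is then drawn as a complete
weighted graph over the panel, its *parenclitic network*, with edge
weights

w(cg_i, cg_j) = min_n d_M((β_i, β_j), μ_n; Σ_n),

the Mahalanobis distance to the closest mixture component. A sample that
behaves like the reference has a uniformly light network; coordinated
deviations light up edges across the graph. The weighted node degree of
each locus feeds an L2-regularised logistic regression (aggressive =
positive class), evaluated on an independent cohort; loci in the top 5% of
|coefficient| are the candidate markers, each labelled by whether a higher
node degree increases or decreases the predicted probability of
aggressive disease.

Because real cohorts for this phenotype are controlled-access, the package
ships a synthetic-data module that generates beta matrices with the same
statistical structure (bimodal pole clusters, intermediate loci,
correlated locus pairs, planted perturbations in aggressive samples), so
the whole pipeline is testable end to end.

## Worked example

```python
from parenclitic import default_scenario

res, truth = default_scenario(seed=0)   # ~2 min: 19,900 pair fits
print(res.summary())
```

```
Parenclitic deviation-network classifier
========================================
panel loci (k)          200
locus pairs modelled    19900
mixture components      1: 1922 pairs, 2: 13026 pairs, 3: 4338 pairs, 4: 614 pairs
feature                 degree
seed                    0

cohorts
  evaluation  aggressive      14
  evaluation  non_aggressive  20
  modeling    non_aggressive  141
  training    aggressive      16
  training    non_aggressive  16

Evaluation (positive class = aggressive)
  samples            34
  accuracy           1.000
  balanced accuracy  1.000
  F1                 1.000
  ROC-AUC            1.000
  confusion          TN=20 FP=0 FN=0 TP=14
```

Reading this: 141 non-aggressive samples fitted the 19,900 pair mixtures
(most pairs need 2 components — the two poles of a locus); networks were
built for the 32 training and 34 held-out evaluation samples; the degree
classifier separates the held-out cohort perfectly at this effect size
(0.3 beta units at 20 planted loci — a strong, fully penetrant
perturbation; real signals are weaker). `res.candidates` lists the top-5%
loci with coefficients, direction and annotation; with this seed all 10
are planted loci (`truth.planted_loci`).

The same model-object API works on real data:

```python
from parenclitic import BetaMatrix, ParencliticModel, read_phenotype_table

beta = BetaMatrix.read("betas.tsv")          # loci x samples, values in [0, 1]
phen = read_phenotype_table("phenotypes.tsv")  # label + cohort per sample
res = ParencliticModel(beta, phen, panel_size=1000).fit(seed=0)
res.evaluation.roc_auc, res.candidates
```

A `parenclitic` command-line tool exposes each stage (`simulate`, `qc`,
`select-panel`, `fit-baseline`, `build-networks`, `features`, `train`,
`evaluate`, `candidates`, `dm-compare`) and a one-shot `run-all` driven by
a YAML config; every stage writes a manifest with content digests, and a
rerun with the same config reproduces byte-identical artifacts.

Quality control (detection-p filters, failed-sample removal, SNP/non-CpG/
sex-chromosome masks), locus-wise F-test and Mann–Whitney comparators, and
Venn-style gene-overlap counting against external locus lists live in
`parenclitic.io_qc` and `parenclitic.diffmeth`.

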