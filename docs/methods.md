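# Methods

## The model

The package classifies DNA methylation array samples (beta values
β ∈ [0, 1] per CpG locus) as *aggressive* or *non-aggressive* by measuring
how far each sample deviates from a reference model of the non-aggressive
population, jointly over pairs of loci.

**Baseline.** For a panel of k loci (default: the k = 1000 most variable
loci of the source cohort; the bundled synthetic study uses k = 200), every
unordered pair (cg_i, cg_j) receives a bivariate Gaussian mixture with up
to four full-covariance components, fitted by EM to the reference
("modeling") cohort's points (β_i, β_j). Four components suffice to
represent the joint methylation states of a pair — both poles of each locus
— plus intermediate patterns. The number of components n ∈ {1, …, 4} is
chosen per pair by the Bayesian information criterion; candidates whose EM
did not converge are never selected.

**Deviation networks.** Each sample becomes a complete weighted graph on
the panel: nodes are loci and the edge weight is the Mahalanobis distance
from the sample's pair point to the *closest* mixture component,

    w(cg_i, cg_j) = min_n sqrt((x − μ_n)ᵀ Σ_n⁻¹ (x − μ_n)),
    x = (β_{cg_i}, β_{cg_j}).

Each candidate component is measured with its own fitted covariance; the
closest component is the argmin of that distance. Alternatives (pooled
covariance; assigning by posterior responsibility and then measuring) exist
but are not the default, because the min-distance form degrades gracefully
when components overlap and is exactly zero on every component mean.
Networks are kept complete — no pruning — since the weights themselves are
already calibrated deviations; an optional prune-below-ε exists but
defaults off.

**Features and classifier.** Per-node topological features summarise each
network: weighted node degree (sum of incident edge weights), degree
centrality above a presence threshold, eigenvector centrality (power
iteration on the weight matrix, unit-norm), weighted-shortest-path
betweenness and eccentricity (edge weight used directly as path length:
larger deviation = longer edge), and second-order centrality (standard
deviation of random-walk return times, computed in closed form from the
fundamental matrix Z = (I − P + 1πᵀ)⁻¹ via E[T_v] = 1/π_v and
E[T_v²] = (2 Z_vv/π_v − 1)/π_v). Node degree is the classifier input: an
L2-regularised logistic regression (C = 1, raw feature scale, aggressive =
positive class) trained on held-out source samples and evaluated on an
independent cohort with accuracy, balanced accuracy, F1 and rank-based
ROC-AUC at a 0.5 probability threshold. Candidate loci are the
ceil(0.05 · k) loci with largest |coefficient|; a positive coefficient
means higher node degree increases the predicted probability of the
aggressive phenotype.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| panel k | 1000 (200 in the synthetic study) | loci | cost grows as k²/2 pairs; variance ranking keeps reproducible loci |
| max_components | 4 | — | the four joint methylation states of a locus pair |
| covariance floor | 1e-6 | beta² | betas pile up at the poles; keeps Σ invertible |
| EM tol | 1e-3 | mean per-point log-lik | matches the convergence scale of standard EM implementations |
| restarts (n_init) | 3 | — | k-means++ seeding; best likelihood kept |
| detection α | 0.05 | p-value | an observation *fails* detection when p ≥ α |
| failed-sample cut | 0.10 | fraction | samples with strictly more than 10% failed probes are dropped |
| classifier C | 1.0 | inverse L2 strength | features used on their raw scale |
| top_fraction | 0.05 | of panel | candidate set size ceil(0.05·k) |

## Numerical choices

* **Batched EM.** A run needs C(k, 2) independent small mixture fits
  (19,900 at k = 200), so EM is vectorised across pairs: all fits of a
  chunk advance together through closed-form 2×2 E/M algebra, converged
  fits leaving the active set each iteration. Restarts follow the
  short-runs/long-runs strategy: every k-means++ restart runs 6 burn-in
  iterations, then only the best-likelihood restart continues to
  convergence. The EM itself runs in single precision (its tolerance is
  ~1e4 times float32 noise); final parameters are stored in double
  precision, and all distance evaluations downstream are double precision.
* **Determinism.** Every source of randomness flows from one master seed.
  Per-pair initialisation uniforms come from a counter-based hash
  (splitmix64) of (master_seed, i, j), so a fit is a pure function of its
  key and data — independent of chunk size, execution order or worker
  count. For the same reason no multiprocessing switch is exposed: the
  vectorised single-process path is already order-free, and its results
  are bit-reproducible across reruns.
* **Ties and degeneracies.** Variance ranking and candidate ranking break
  ties lexicographically by locus id. Constant pair data yields a single
  component with mean equal to the point and covariance floor·I. All-tied
  groups in rank tests get p = 1 by convention. BIC ties resolve to the
  smaller component count.
* **Serialization.** The baseline archive is a JSON header plus raw
  little-endian array bytes — deliberately not a zip container, whose
  embedded timestamps would break byte-identical reruns.

## The synthetic data generator

Real cohorts for this phenotype are controlled-access, so the generator
emulates the features of array data the method relies on: (i) most loci
are constitutively methylated or unmethylated — Beta(c, 9c) or Beta(9c, c)
pole clusters with c = 8 (SD ≈ 0.033, the tight "little variation" pole
clusters seen on arrays, and close enough to Gaussian that one mixture
component represents one state); (ii) a fraction (default 10%) of loci
have intermediate methylation, Beta(10c, 10c); (iii) the planted loci are
*polymorphic* — each sample occupies one pole, with blocks of two planted
loci sharing a latent state per sample, which gives their joint
distributions genuine two-cluster structure and makes them the
high-variance loci a variance-ranked panel recovers; (iv) aggressive
samples are perturbed at every planted locus by a bounded logit-space
shift, calibrated numerically so the majority-state cluster mean moves by
`effect_size` (default 0.3) beta units toward the opposite pole — logit
space keeps values inside (0, 1) at any effect size.

The default study design mirrors the modelled setting: 141 baseline
non-aggressive samples (mixture fitting only), 16 aggressive + 16
non-aggressive training samples from the same source, and an independent
evaluation set of 14 aggressive + 20 non-aggressive samples, over
n_loci = 200 with 20 planted loci. These sizes also keep a full run
(~20k pair fits) around two minutes on one core, which is why the bundled
study uses a 200-locus panel rather than 1000.

**What the generator does not emulate** — probe chemistry, dye/channel
effects, batch structure, genomic autocorrelation of methylation, and
realistic linkage between annotation categories and methylation state.
Passing tests therefore demonstrate that the pipeline recovers planted
joint-distribution perturbations under the assumed data model, not that it
classifies real tumours at any particular accuracy.

## Open design points resolved here

* The weight formula names component means only; a Mahalanobis distance
  needs a covariance, and the component's own full covariance is used (see
  above).
* Component-count selection is by BIC; the selection criterion, covariance
  structure and EM initialisation are this package's decisions, not
  reconstructions of any particular prior implementation.
* Degree centrality is identically 1 on complete positive-weight graphs,
  so it takes a presence threshold ε (default 0) and is reported per node;
  eccentricity is likewise reported per node.
* Variance ranking for the panel uses all samples of the designated
  selection cohort (modeling + training by default; configurable), since
  the reference cohort alone would ignore the training samples' loci.
* dmpFinder-style comparison is implemented as a plain two-group F test
  per locus (the squared two-sample t) with Benjamini–Hochberg control at
  q < 0.05 by default; shrinkage refinements of specific R implementations
  are out of scope.

## Known limitations

* Cost is quadratic in the panel size; k = 1000 means ~500k pair fits and
  is a batch job, not an interactive one.
* The Gaussian mixture approximates skewed Beta-distributed pole clusters;
  with very diffuse clusters (small state concentration) BIC may spend an
  extra component on skewness. The deviation weights remain well defined
  either way.
* The classifier is linear in one topological feature by design —
  interpretability over raw accuracy; no classifier-comparison harness is
  provided as a supported path.
* With 30–34 evaluation samples the binomial noise on reported metrics is
  a few percentage points; replicate seeds (as the acceptance script does)
  before comparing configurations.
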