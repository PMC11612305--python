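"""Synthetic DNA methylation datasets with planted group differences.

The generator emulates the statistical structure that the parenclitic
pipeline assumes of array beta values:

* most CpG loci are *constitutively* methylated or unmethylated — every
  sample's beta value clusters near 1 or near 0 with little variation;
* a minority of loci have *intermediate* methylation (betas around 0.5);
* the planted loci are *polymorphic*: each sample occupies one of the two
  pole states, and planted loci are grouped into blocks that share a latent
  state per sample, so their joint (pairwise) distribution has genuine
  multi-component structure for the mixture baseline to recover;
* "aggressive" samples are perturbed at the planted loci by a bounded
  logit-space shift whose magnitude is calibrated so the majority-state
  cluster mean moves by ``effect_size`` in beta units.

Pole states are Beta(c, 9c) (mean 0.1) and Beta(9c, c) (mean 0.9) with
``c = state_concentration``; intermediate loci are Beta(10c, 10c). The
default concentration (c = 8, pole standard deviation ~0.033) reflects the
tight pole clusters of real array betas and keeps each pole cluster close
enough to Gaussian for the pairwise mixture baseline to represent it with a
single component.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .io_qc import BetaMatrix, DetectionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_annotation",
]

_EPS = 1e-6


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the modelled study: 141 baseline (non-aggressive)
    samples for the mixture model, a 16 aggressive / 16 non-aggressive
    training set from the same source, and an independent evaluation set of
    14 aggressive / 20 non-aggressive samples; a 200-locus panel with 20
    planted loci perturbed by 0.3 beta units in aggressive samples.
    """

    n_baseline: int = 141
    n_train_pos: int = 16
    n_train_neg: int = 16
    n_eval_pos: int = 14
    n_eval_neg: int = 20
    n_loci: int = 200
    n_planted: int = 20
    effect_size: float = 0.3
    state_concentration: float = 8.0
    frac_intermediate: float = 0.1
    fail_rate: float = 0.0
    seed: int = 0
    #: probability that a sample occupies the rarer pole of a planted block
    minority_fraction: float = 0.1

    def validate(self) -> None:
        for name in ("n_baseline", "n_train_pos", "n_train_neg", "n_eval_pos",
                     "n_eval_neg", "n_loci", "n_planted"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_planted > self.n_loci:
            raise ConfigError(
                f"n_planted ({self.n_planted}) must not exceed n_loci ({self.n_loci})")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigError(f"effect_size must lie in [0, 1], got {self.effect_size!r}")
        if not 0.0 <= self.frac_intermediate <= 1.0:
            raise ConfigError(
                f"frac_intermediate must lie in [0, 1], got {self.frac_intermediate!r}")
        if not 0.0 <= self.fail_rate < 1.0:
            raise ConfigError(f"fail_rate must lie in [0, 1), got {self.fail_rate!r}")
        if not 0.0 <= self.minority_fraction <= 0.5:
            raise ConfigError(
                f"minority_fraction must lie in [0, 0.5], got {self.minority_fraction!r}")
        if self.state_concentration <= 0:
            raise ConfigError(
                f"state_concentration must be positive, got {self.state_concentration!r}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")

    @property
    def n_samples(self) -> int:
        return (self.n_baseline + self.n_train_pos + self.n_train_neg
                + self.n_eval_pos + self.n_eval_neg)


@dataclass
class SyntheticTruth:
    """Ground truth of the planted perturbation."""

    planted_loci: list[str]
    directions: dict[str, int]  # probe id -> +1 (beta increases) / -1
    blocks: list[list[str]] = field(default_factory=list)  # state-sharing groups
    intermediate_loci: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["directions"] = {k: int(v) for k, v in d["directions"].items()}
        return cls(**d)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrated_logit_shift(c: float, pole: int, effect: float, direction: int) -> float:
    """Logit-space offset whose *expected* beta-scale shift equals ``effect``.

    A constant logit offset moves different beta values by different amounts
    (the sigmoid is curved), so the offset is solved numerically such that
    the mean of the majority-state cluster Beta(c, 9c) (or its mirror)
    moves by exactly ``effect`` in the requested direction.
    """
    from scipy.stats import beta as beta_dist

    a, b = (c, 9.0 * c) if pole == 0 else (9.0 * c, c)
    grid = beta_dist(a, b).ppf((np.arange(4000) + 0.5) / 4000)
    base = grid.mean()
    target = float(np.clip(base + direction * effect, 1e-3, 1.0 - 1e-3))
    lg = _logit(grid)

    def shifted_mean(delta: float) -> float:
        return float(_expit(lg + delta).mean())

    # shifted_mean is increasing in delta, so plain bisection brackets both signs
    lo, hi = (0.0, 60.0) if direction > 0 else (-60.0, 0.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if shifted_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SyntheticConfig):
    """Generate ``(BetaMatrix, DetectionMatrix, phenotypes, SyntheticTruth)``.

    The phenotype table is a DataFrame indexed by sample id with columns
    ``label`` (aggressive / non_aggressive), ``cohort`` (modeling / training /
    evaluation) and ``source`` (discovery / validation). Identical configs
    (including the seed) produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, S = config.n_loci, config.n_samples
    c = config.state_concentration

    probe_ids = [f"cg{i:08d}" for i in range(L)]
    sample_ids = [f"s{i:04d}" for i in range(S)]

    # --- cohort layout ------------------------------------------------------
    labels, cohorts, sources = [], [], []
    for n, lab, coh, src in (
        (config.n_baseline, "non_aggressive", "modeling", "discovery"),
        (config.n_train_neg, "non_aggressive", "training", "discovery"),
        (config.n_train_pos, "aggressive", "training", "discovery"),
        (config.n_eval_neg, "non_aggressive", "evaluation", "validation"),
        (config.n_eval_pos, "aggressive", "evaluation", "validation"),
    ):
        labels += [lab] * n
        cohorts += [coh] * n
        sources += [src] * n
    phenotypes = pd.DataFrame(
        {"label": labels, "cohort": cohorts, "source": sources},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    aggressive = (phenotypes["label"] == "aggressive").to_numpy()

    # --- locus classes ------------------------------------------------------
    planted_idx = np.sort(rng.choice(L, size=config.n_planted, replace=False))
    remaining = np.setdiff1d(np.arange(L), planted_idx)
    n_int = int(round(config.frac_intermediate * L))
    n_int = min(n_int, remaining.size)
    inter_idx = np.sort(rng.choice(remaining, size=n_int, replace=False)) if n_int else np.array([], int)
    const_idx = np.setdiff1d(remaining, inter_idx)

    planted_pole = rng.integers(0, 2, size=config.n_planted)  # 0 = near-0 majority
    const_pole = rng.integers(0, 2, size=const_idx.size)

    # planted loci in consecutive blocks of two share a latent state
    blocks = [planted_idx[i:i + 2] for i in range(0, config.n_planted, 2)]
    minority = rng.random((len(blocks), S)) < config.minority_fraction

    raw0 = rng.beta(c, 9.0 * c, size=(L, S))        # near-0 pole
    raw1 = rng.beta(9.0 * c, c, size=(L, S))        # near-1 pole
    rawm = rng.beta(10.0 * c, 10.0 * c, size=(L, S))  # intermediate

    pole = np.zeros((L, S), dtype=bool)  # True = near-1 state
    pole[const_idx] = (const_pole == 1)[:, None]
    for b, block in enumerate(blocks):
        for locus in block:
            k = int(np.where(planted_idx == locus)[0][0])
            pole[locus] = (planted_pole[k] == 1) ^ minority[b]

    beta = np.where(pole, raw1, raw0)
    if inter_idx.size:
        beta[inter_idx] = rawm[inter_idx]

    # --- planted perturbation (bounded logit shift) -------------------------
    directions: dict[str, int] = {}
    for k, locus in enumerate(planted_idx):
        d = 1 if planted_pole[k] == 0 else -1  # push majority pole inward
        directions[probe_ids[locus]] = d
        if config.effect_size > 0:
            delta = _calibrated_logit_shift(c, int(planted_pole[k]),
                                            config.effect_size, d)
            beta[locus, aggressive] = _expit(_logit(beta[locus, aggressive]) + delta)

    # --- detection p-values -------------------------------------------------
    det = rng.uniform(0.0, 0.04, size=(L, S))
    if config.fail_rate > 0:
        failed = rng.random((L, S)) < config.fail_rate
        det[failed] = rng.uniform(0.05, 1.0, size=(L, S))[failed]
        beta[failed] = np.nan

    beta_m = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=sample_ids))
    det_m = DetectionMatrix(pd.DataFrame(det, index=probe_ids, columns=sample_ids))
    truth = SyntheticTruth(
        planted_loci=[probe_ids[i] for i in planted_idx],
        directions=directions,
        blocks=[[probe_ids[i] for i in block] for block in blocks],
        intermediate_loci=[probe_ids[i] for i in inter_idx],
        seed=config.seed,
    )
    return beta_m, det_m, phenotypes, truth


_TFBS_POOL = ["K562 CTCF", "GM12878 POLR2A", "HepG2 POLR2A", "H1-hESC YY1",
              "IMR90 CEBPB", "K562 IKZF1"]


def generate_annotation(probe_ids, seed: int = 0, exclude_from_masks=None) -> pd.DataFrame:
    """Synthetic probe annotation exercising every QC mask category.

    Columns: ``chromosome``, ``gene``, ``is_snp``, ``is_cpg``, ``enhancer``,
    ``tfbs``. For ``len(probe_ids) >= 20`` at least one probe falls in each
    mask category (SNP, non-CpG, sex chromosome). Probes listed in
    ``exclude_from_masks`` are guaranteed to survive all masks (autosomal,
    SNP-free, CpG), which is how planted candidate loci are kept maskable-free
    in simulated pipelines.
    """
    probe_ids = list(probe_ids)
    if not probe_ids:
        raise ValidationError("probe_ids must be non-empty")
    if len(set(probe_ids)) != len(probe_ids):
        dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    exclude = set(exclude_from_masks or ())
    rng = np.random.default_rng(seed)
    n = len(probe_ids)

    autosomes = [f"chr{i}" for i in range(1, 23)]
    chrom = rng.choice(autosomes, size=n).astype(object)
    sex_draw = rng.random(n)
    chrom[sex_draw < 0.04] = "chrX"
    chrom[(sex_draw >= 0.04) & (sex_draw < 0.06)] = "chrY"
    is_snp = rng.random(n) < 0.05
    is_cpg = rng.random(n) >= 0.03
    enhancer = rng.random(n) < 0.20
    gene_pool = [f"GENE{i:04d}" for i in range(max(10, n // 3))]
    gene = np.where(rng.random(n) < 0.6, rng.choice(gene_pool, size=n), "").astype(object)
    tfbs = np.where(rng.random(n) < 0.15, rng.choice(_TFBS_POOL, size=n), "").astype(object)

    ann = pd.DataFrame(
        {"chromosome": chrom, "gene": gene, "is_snp": is_snp,
         "is_cpg": is_cpg, "enhancer": enhancer, "tfbs": tfbs},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    if exclude:
        keep = ann.index.isin(exclude)
        ann.loc[keep, "chromosome"] = "chr1"
        ann.loc[keep, "is_snp"] = False
        ann.loc[keep, "is_cpg"] = True

    if n >= 20:  # guarantee every mask category is represented
        eligible = ann.index[~ann.index.isin(exclude)]
        if eligible.size:
            if not ann["is_snp"].any():
                ann.loc[eligible[0], "is_snp"] = True
            if ann["is_cpg"].all():
                ann.loc[eligible[1 % eligible.size], "is_cpg"] = False
            if not ann["chromosome"].isin(["chrX", "chrY"]).any():
                ann.loc[eligible[2 % eligible.size], "chromosome"] = "chrX"
    return ann
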