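"""High-level modelling interface: build from data, ``fit()``, inspect results.

``ParencliticModel`` bundles the full procedure — variance-ranked panel
selection, per-pair mixture baseline on the reference cohort, per-sample
deviation networks, topological feature extraction, logistic-regression
training and held-out evaluation — behind a single ``fit`` call that
returns a :class:`ParencliticResults` carrying estimates, diagnostics and a
``summary()`` table.

Example
-------
>>> from parenclitic import ParencliticModel, SyntheticConfig, generate_dataset
>>> beta, det, phen, truth = generate_dataset(SyntheticConfig(seed=1))
>>> res = ParencliticModel(beta, phen, panel_size=200).fit(seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baseline import fit_baseline
from .classify import candidate_loci, evaluate, split_cohorts, train
from .exceptions import ValidationError
from .gmm import GMMSettings
from .io_qc import BetaMatrix, validate_phenotypes
from .networks import build_networks
from .panel import top_variant_loci
from .topology import feature_matrix

__all__ = ["ParencliticModel", "ParencliticResults"]


class ParencliticModel:
    """Deviation-network phenotype classifier over a methylation matrix.

    Parameters
    ----------
    beta :
        Loci x samples :class:`BetaMatrix` (post-QC).
    phenotypes :
        DataFrame indexed by sample id with ``label`` and, unless
        ``n_modeling`` is given, ``cohort`` columns.
    annotation :
        Optional probe annotation used to annotate candidate loci.
    panel_size :
        Number of top-variance loci to model (k).
    variance_cohort :
        Which samples rank the panel: ``"discovery"`` (modeling + training,
        i.e. the source dataset), ``"modeling"``, or ``"all"``.
    n_modeling :
        When the phenotype table has no cohort roles, randomly assign this
        many non-aggressive samples to the modeling cohort at ``fit`` time.
    """

    def __init__(self, beta: BetaMatrix, phenotypes: pd.DataFrame,
                 annotation: pd.DataFrame | None = None, *,
                 panel_size: int = 1000,
                 variance_cohort: str = "discovery",
                 n_modeling: int | None = None,
                 feature: str = "degree",
                 feature_params: dict | None = None,
                 gmm_settings: GMMSettings | None = None,
                 C: float = 1.0,
                 standardize: bool = False,
                 top_fraction: float = 0.05):
        validate_phenotypes(phenotypes)
        missing = [s for s in phenotypes.index if s not in set(beta.sample_ids)]
        if missing:
            raise ValidationError(
                f"phenotype samples absent from beta matrix: {missing[:10]}")
        if variance_cohort not in ("discovery", "modeling", "all"):
            raise ValidationError(
                f"variance_cohort must be discovery/modeling/all, got {variance_cohort!r}")
        self.beta = beta
        self.phenotypes = phenotypes
        self.annotation = annotation
        self.panel_size = panel_size
        self.variance_cohort = variance_cohort
        self.n_modeling = n_modeling
        self.feature = feature
        self.feature_params = dict(feature_params or {})
        self.gmm_settings = gmm_settings or GMMSettings()
        self.C = C
        self.standardize = standardize
        self.top_fraction = top_fraction

    @classmethod
    def from_dataframes(cls, beta_frame: pd.DataFrame, phenotypes: pd.DataFrame,
                        **kwargs) -> "ParencliticModel":
        """Construct from a plain loci x samples DataFrame."""
        return cls(BetaMatrix(beta_frame), phenotypes, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, seed: int = 0) -> "ParencliticResults":
        phen = self.phenotypes
        if "cohort" not in phen.columns or phen["cohort"].isna().any() \
                or (phen["cohort"] == "").any():
            if self.n_modeling is None:
                raise ValidationError(
                    "phenotypes lack cohort roles; pass n_modeling to split them")
            phen = split_cohorts(phen, self.n_modeling, seed=seed)

        modeling = phen.index[phen["cohort"] == "modeling"].tolist()
        training = phen.index[phen["cohort"] == "training"].tolist()
        evaluation = phen.index[phen["cohort"] == "evaluation"].tolist()
        if not modeling or not training:
            raise ValidationError("modeling and training cohorts must be non-empty")
        if set(modeling) & set(training):
            raise ValidationError("modeling and training cohorts overlap")

        if self.variance_cohort == "all":
            var_samples = phen.index.tolist()
        elif self.variance_cohort == "modeling":
            var_samples = modeling
        else:  # the full source dataset
            var_samples = modeling + training
        panel = top_variant_loci(self.beta, self.panel_size, samples=var_samples)

        baseline = fit_baseline(self.beta.select_samples(modeling), panel,
                                settings=self.gmm_settings, master_seed=seed)
        nets = build_networks(self.beta, baseline, sample_ids=training + evaluation)
        fm = feature_matrix(nets, self.feature, self.feature_params)

        clf = train(
            type(fm)(name=fm.name, frame=fm.frame.loc[training], params=fm.params),
            phen.loc[training, "label"], C=self.C,
            standardize=self.standardize, seed=seed)
        report = None
        if evaluation:
            report = evaluate(clf, fm.frame.loc[evaluation],
                              phen.loc[evaluation, "label"])
        candidates = candidate_loci(clf, self.annotation, self.top_fraction)
        return ParencliticResults(
            model=self, phenotypes=phen, panel=panel, baseline=baseline,
            networks=nets, features=fm, classifier=clf, evaluation=report,
            candidates=candidates, seed=seed)


class ParencliticResults:
    """Fitted baseline, classifier, evaluation metrics and candidate table."""

    def __init__(self, model, phenotypes, panel, baseline, networks, features,
                 classifier, evaluation, candidates, seed):
        self.model = model
        self.phenotypes = phenotypes
        self.panel = panel
        self.baseline = baseline
        self.networks = networks
        self.features = features
        self.classifier = classifier
        self.evaluation = evaluation
        self.candidates = candidates
        self.seed = seed

    @property
    def coefficients(self) -> pd.Series:
        return self.classifier.coef

    def summary(self) -> str:
        phen = self.phenotypes
        counts = phen.groupby(["cohort", "label"]).size()
        comp, freq = np.unique(self.baseline.n_components, return_counts=True)
        lines = [
            "Parenclitic deviation-network classifier",
            "========================================",
            f"panel loci (k)          {len(self.panel)}",
            f"locus pairs modelled    {self.baseline.n_pairs}",
            "mixture components      "
            + ", ".join(f"{int(c)}: {int(f)} pairs" for c, f in zip(comp, freq)),
            f"feature                 {self.features.name}",
            f"seed                    {self.seed}",
            "",
            "cohorts",
        ]
        for (cohort, label), n in counts.items():
            lines.append(f"  {cohort:<11} {label:<15} {int(n)}")
        if self.evaluation is not None:
            lines += ["", str(self.evaluation).rstrip()]
        lines += ["", f"top candidate loci (|coef| top {self.model.top_fraction:.0%})"]
        for locus, row in self.candidates.head(10).iterrows():
            lines.append(f"  {locus}  {row['coefficient']:+.4g}  {row['direction']}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the held-out evaluation (requires matplotlib)."""
        if self.evaluation is None:
            raise ValidationError("no evaluation cohort was scored")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.evaluation.roc_points
        ax.plot(pts["fpr"], pts["tpr"],
                label=f"ROC-AUC = {self.evaluation.roc_auc:.2f}")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
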