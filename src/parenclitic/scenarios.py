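"""Ready-made synthetic study scenarios used by examples and benchmarks."""

from __future__ import annotations

from .model import ParencliticModel, ParencliticResults
from .synthetic import SyntheticConfig, SyntheticTruth, generate_annotation, generate_dataset

__all__ = ["default_scenario"]


def default_scenario(seed: int = 0, config: SyntheticConfig | None = None,
                     ) -> tuple[ParencliticResults, SyntheticTruth]:
    """Generate the default synthetic cohort and fit the full model on it.

    The default :class:`SyntheticConfig` study design: 141 baseline
    non-aggressive samples, a 16/16 training set, an independent 14/20
    evaluation set, a 200-locus panel with 20 planted loci perturbed by 0.3
    beta units. Returns the fitted results together with the generator's
    ground truth.
    """
    cfg = config or SyntheticConfig(seed=seed)
    beta, _det, phen, truth = generate_dataset(cfg)
    annotation = generate_annotation(beta.probe_ids, seed=cfg.seed,
                                     exclude_from_masks=truth.planted_loci)
    model = ParencliticModel(beta, phen, annotation=annotation,
                             panel_size=cfg.n_loci)
    return model.fit(seed=seed), truth
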