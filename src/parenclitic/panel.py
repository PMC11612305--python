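"""Locus panel selection by cross-sample variance ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io_qc import BetaMatrix

log = logging.getLogger(__name__)

__all__ = ["LocusPanel", "top_variant_loci", "read_panel", "write_panel"]


@dataclass(frozen=True)
class LocusPanel:
    """Ordered list of probe ids with selection provenance."""

    loci: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("panel loci must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)


def top_variant_loci(beta: BetaMatrix, k: int, samples=None) -> LocusPanel:
    """The ``k`` probes with largest (n-1 denominator) beta variance.

    Variance is computed over ``samples`` (default: all samples of the
    matrix). Ordering is by descending variance, ties broken by ascending
    probe id, which makes selection deterministic and independent of sample
    order.
    """
    frame = beta.frame if samples is None else beta.frame[list(samples)]
    if k > frame.shape[0]:
        raise ValidationError(f"k ({k}) exceeds the number of probes ({frame.shape[0]})")
    values = frame.to_numpy()
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)].tolist()
        raise ValidationError(f"missing beta values at loci: {bad[:10]}")
    var = values.var(axis=1, ddof=1)
    if np.all(var == 0):
        log.warning("all probe variances are zero; panel ranking is degenerate")
    order = sorted(range(len(var)), key=lambda i: (-var[i], frame.index[i]))
    chosen = [frame.index[i] for i in order[:k]]
    return LocusPanel(
        loci=tuple(chosen),
        provenance={"k": k, "n_samples": frame.shape[1],
                    "tie_rule": "descending variance, then probe id"},
    )


def write_panel(panel: LocusPanel, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(panel.provenance):
            fh.write(f"# {key}: {panel.provenance[key]}\n")
        for locus in panel.loci:
            fh.write(locus + "\n")


def read_panel(path) -> LocusPanel:
    loci, provenance = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                provenance[key.strip()] = value.strip()
            else:
                loci.append(line)
    return LocusPanel(loci=tuple(loci), provenance=provenance)
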