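"""Locus-wise differential methylation comparators and gene-overlap counts.

These are the conventional per-locus analyses the network approach is
contrasted with: a two-group F test per locus (the squared two-sample t in
this case), a Mann-Whitney test, and Venn-style overlap counting between
gene lists derived from different methods.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io_qc import BetaMatrix

__all__ = ["per_locus_ftest", "per_locus_mannwhitney", "gene_overlap"]


def _group_values(beta, labels):
    frame = beta.frame if isinstance(beta, BetaMatrix) else beta
    lab = pd.Series(labels)
    if set(frame.columns) <= set(lab.index):
        lab = lab.reindex(frame.columns)
    if len(lab) != frame.shape[1]:
        raise ValidationError("labels do not align with the matrix samples")
    pos = frame.loc[:, (lab == "aggressive").to_numpy()].to_numpy()
    neg = frame.loc[:, (lab == "non_aggressive").to_numpy()].to_numpy()
    return frame, pos, neg


def per_locus_ftest(beta, labels) -> pd.DataFrame:
    """One-way two-group F statistic per locus with BH adjustment.

    Loci where both groups are constant and equal get p = 1 by convention.
    Returns a DataFrame indexed by locus with columns ``F``, ``p``, ``q``,
    ``mean_aggressive`` and ``mean_non_aggressive``.
    """
    frame, pos, neg = _group_values(beta, labels)
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples for an F test")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = f_oneway(pos, neg, axis=1)
    degenerate = ~np.isfinite(p)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "F": stat, "p": p, "q": q,
        "mean_aggressive": pos.mean(axis=1),
        "mean_non_aggressive": neg.mean(axis=1),
    }, index=pd.Index(frame.index, name="locus"))


def per_locus_mannwhitney(beta, labels, loci_subset=None) -> pd.Series:
    """Two-sided Mann-Whitney p per locus (exact for small tie-free groups).

    ``scipy``'s method='auto' policy applies: the exact null distribution is
    enumerated for small groups without ties, otherwise the tie-corrected
    normal approximation is used. All-tied loci get p = 1.
    """
    frame, pos, neg = _group_values(beta, labels)
    if pos.shape[1] == 0 or neg.shape[1] == 0:
        raise ValidationError("both groups must be non-empty")
    if loci_subset is not None:
        loci_subset = list(loci_subset)
        missing = [l for l in loci_subset if l not in frame.index]
        if missing:
            raise ValidationError(f"unknown loci: {missing[:10]}")
        keep = frame.index.get_indexer(loci_subset)
        frame, pos, neg = frame.iloc[keep], pos[keep], neg[keep]
    combined = np.hstack([pos, neg])
    tied = np.ptp(combined, axis=1) == 0
    p = np.ones(frame.shape[0])
    if (~tied).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(pos[~tied], neg[~tied], axis=1,
                               alternative="two-sided", method="auto")
        p[~tied] = np.nan_to_num(res.pvalue, nan=1.0)
    return pd.Series(p, index=pd.Index(frame.index, name="locus"), name="p")


def gene_overlap(sets: dict, annotation: pd.DataFrame | None = None,
                 map_loci: bool | None = None) -> dict:
    """Cardinality of every Venn region over named gene sets.

    Each entry of ``sets`` is a collection of locus ids (mapped to gene
    symbols through ``annotation``; loci without a gene are dropped) or of
    gene symbols directly (when no annotation is given, or ``map_loci`` is
    False). Returns ``{frozenset of set names: count}`` covering all
    non-empty membership patterns, e.g. ``{A}``: genes only in A,
    ``{A, B}``: genes in exactly A and B.
    """
    if map_loci is None:
        map_loci = annotation is not None
    gene_sets: dict[str, set] = {}
    for name, items in sets.items():
        items = list(items)
        if map_loci:
            if annotation is None:
                raise ValidationError("an annotation is required to map loci to genes")
            unknown = [x for x in items if x not in annotation.index]
            if unknown:
                raise ValidationError(f"unknown loci in set {name!r}: {unknown[:10]}")
            genes = {g for g in annotation.loc[items, "gene"] if g}
        else:
            genes = set(items)
        gene_sets[name] = genes

    names = list(gene_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(gene_sets[n] for n in inside))
            for outside in names:
                if outside not in inside:
                    region -= gene_sets[outside]
            regions[frozenset(inside)] = len(region)
    return regions
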