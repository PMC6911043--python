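"""Cross-layer statistics: fold-change classification of binding and
expression, binding-expression concordance, binding-splicing cluster-switch
co-association, and cohort-genetics contingency tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .splicing import ContingencyResult, fisher_2x2

CLASSES = ("mut_preferred", "wt_preferred", "neutral")


def fold_change_classes(values_wt, values_mut, fc: float = 1.5,
                        pseudocount: float = 1.0) -> np.ndarray:
    """Classify genes by the mutant/wild-type ratio with a 1.5-fold cutoff.

    mut_preferred if (mut + eps)/(wt + eps) > fc; wt_preferred if < 1/fc;
    neutral otherwise.  ``pseudocount`` guards zeros (1 count for CLIP
    tallies; use ~0.1 for abundance units).
    """
    wt = np.asarray(values_wt, dtype=float)
    mut = np.asarray(values_mut, dtype=float)
    if (wt < 0).any() or (mut < 0).any():
        raise ValidationError("values must be nonnegative")
    ratio = (mut + pseudocount) / (wt + pseudocount)
    return np.where(ratio > fc, "mut_preferred",
                    np.where(ratio < 1 / fc, "wt_preferred", "neutral"))


@dataclass
class ConcordanceResult:
    n_mut_concordant: int    # mut-preferred in both binding and expression
    n_wt_concordant: int
    r_squared: float         # OLS R^2 of log2 expr ratio on log2 binding ratio
    classes: pd.DataFrame


def binding_expression_concordance(gene_quant: pd.DataFrame,
                                   fc: float = 1.5,
                                   clip_pseudocount: float = 1.0,
                                   expr_pseudocount: float = 0.1) -> ConcordanceResult:
    """Intersection of binding- and expression-preferred gene sets plus the
    transcriptome-wide correlation of the two log fold changes."""
    if gene_quant.empty:
        raise ValidationError("empty gene table")
    binding = fold_change_classes(gene_quant["clip_wt"], gene_quant["clip_mut"],
                                  fc, clip_pseudocount)
    expression = fold_change_classes(gene_quant["expr_wt"], gene_quant["expr_mut"],
                                     fc, expr_pseudocount)
    log_bind = np.log2((gene_quant["clip_mut"] + clip_pseudocount)
                       / (gene_quant["clip_wt"] + clip_pseudocount))
    log_expr = np.log2((gene_quant["expr_mut"] + expr_pseudocount)
                       / (gene_quant["expr_wt"] + expr_pseudocount))
    if np.ptp(log_bind) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.linregress(log_bind, log_expr).rvalue ** 2)
    classes = pd.DataFrame({
        "gene_id": gene_quant["gene_id"],
        "binding_class": binding,
        "expression_class": expression,
    })
    return ConcordanceResult(
        n_mut_concordant=int(((binding == "mut_preferred")
                              & (expression == "mut_preferred")).sum()),
        n_wt_concordant=int(((binding == "wt_preferred")
                             & (expression == "wt_preferred")).sum()),
        r_squared=r2,
        classes=classes,
    )


def binding_splicing_coassociation(splicing_calls: pd.DataFrame,
                                   switch_table: pd.DataFrame,
                                   bf_min: float = 10.0,
                                   dpsi_min: float = 0.10) -> ContingencyResult:
    """Fisher co-association of strong differential splicing with binding
    cluster switches.

    Strong events: Bayes factor >= ``bf_min`` and |dpsi| > ``dpsi_min``.
    Events are mapped to the switch table by ``site_id``; unmapped events
    are dropped.
    """
    merged = splicing_calls.merge(switch_table[["site_id", "switch"]], on="site_id")
    if merged.empty:
        raise ValidationError("no splicing events map to the switch table")
    strong = (merged["bayes_factor"] >= bf_min) & (merged["dpsi"].abs() > dpsi_min)
    switch = merged["switch"].astype(bool)
    table = np.array([
        [int((strong & switch).sum()), int((strong & ~switch).sum())],
        [int((~strong & switch).sum()), int((~strong & ~switch).sum())],
    ])
    return fisher_2x2(table)


def cooccurrence_fisher(n_total: int, n_A: int, n_B: int, n_AB: int) -> ContingencyResult:
    """Fisher test of the co-occurrence of two lesions from cohort margins."""
    if not (0 <= n_AB <= min(n_A, n_B) <= max(n_A, n_B) <= n_total):
        raise ValidationError("margins must satisfy n_AB <= min(n_A, n_B) <= n_total")
    table = np.array([
        [n_AB, n_A - n_AB],
        [n_B - n_AB, n_total - n_A - n_B + n_AB],
    ])
    if (table < 0).any():
        raise ValidationError("inconsistent margins (negative cell)")
    return fisher_2x2(table)


def hotspot_binomial_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood convention) for
    observing ``k`` hotspot mutations among ``n``."""
    if n <= 0 or not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n and n > 0")
    if not 0 < p0 < 1:
        raise ValidationError("p0 must be in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
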