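"""Ranked differential-expression signatures from two-condition expression data.

The signature statistic is a per-gene Welch (unequal-variance) two-sample t,
signed so that positive means "up in condition B relative to condition A"
(e.g. adult prostate relative to embryonic urogenital sinus).  Sequencing
counts can first be put on a common scale with median-of-ratios size factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .network import ExpressionMatrix, GeneSignature, SizeFactors, NOT_REPRESENTED

logger = logging.getLogger(__name__)

__all__ = ["median_ratio_normalize", "compute_signature", "signature_de"]


def median_ratio_normalize(
    counts: ExpressionMatrix, pseudocount: float = 0.0
) -> tuple[ExpressionMatrix, SizeFactors]:
    """Median-of-ratios count normalization.

    For every gene with strictly positive counts in all samples, each sample's
    count is divided by the gene's geometric mean across samples; the sample's
    size factor is the median of those ratios, and each column is divided by
    its factor.  Idempotent: renormalizing yields unit factors.

    Parameters
    ----------
    counts
        Non-negative count matrix.
    pseudocount
        Added to every count before computing ratios (off by default; only
        useful when no gene is positive in every sample).
    """
    values = counts.values + pseudocount
    if (values < 0).any().any():
        raise ValueError("normalization requires non-negative counts")
    arr = values.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "consider pseudocount > 0"
        )
    log_geo = np.log(arr[positive]).mean(axis=1, keepdims=True)
    ratios = arr[positive] / np.exp(log_geo)
    raw = np.median(ratios, axis=0)
    # rescale to geometric mean 1: the global scale of median ratios is
    # arbitrary, and this makes normalization exactly idempotent
    factors = pd.Series(raw / np.exp(np.mean(np.log(raw))), index=counts.samples)
    normalized = ExpressionMatrix(counts.values / factors, dict(counts.conditions))
    return normalized, SizeFactors(factors)


def compute_signature(
    expr: ExpressionMatrix, cond_a: str, cond_b: str
) -> GeneSignature:
    """Per-gene Welch t-statistic signature, positive when mean(B) > mean(A).

    Genes with zero variance in both conditions and equal means score 0;
    zero-variance genes with unequal means receive the sign of the mean
    difference at a magnitude just above the largest finite score so that the
    ranking stays well defined.
    """
    for label in (cond_a, cond_b):
        if label not in set(expr.conditions):
            raise ValueError(f"condition label {label!r} absent from matrix")
    a = expr.values[expr.samples_of(cond_a)].to_numpy(float)
    b = expr.values[expr.samples_of(cond_b)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >= 2 samples per condition, got {a.shape[1]} ({cond_a!r}) "
            f"and {b.shape[1]} ({cond_b!r})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(b, a, axis=1, equal_var=False).statistic
    diff = b.mean(axis=1) - a.mean(axis=1)
    # zero variance in both groups: t is 0/0 (equal means) or +-inf-like
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        finite = np.abs(t[~degenerate])
        cap = (finite.max() if finite.size else 0.0) + 1.0
        t = t.copy()
        t[degenerate] = np.where(diff[degenerate] == 0, 0.0, np.sign(diff[degenerate]) * cap)
        logger.info("capped %d zero-variance genes at +-%.4g", int(degenerate.sum()), cap)
    return GeneSignature(pd.Series(t, index=expr.genes))


def signature_de(sig: GeneSignature, gene: str) -> float:
    """Differential expression of *gene* in the signature.

    Returns the gene's signature score, or the NOT_REPRESENTED marker (NaN)
    when the gene was not measured on the platform; absence is a value, not
    an error.
    """
    return sig.score_of(gene)
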