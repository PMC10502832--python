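"""Normalization to TPM, expressed-gene filtering, and replicate QC.

The working transform for correlation and PCA is log2(TPM + 1): standard,
bounded at zero, and damping dropout noise in few-cell samples. PCA is a
singular value decomposition of the centered (not scaled) matrix with
samples as observations and genes as features; component signs are fixed
deterministically by making the largest-magnitude gene loading positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneModel, ValidationError

logger = logging.getLogger("tescope")

__all__ = ["QCReport", "counts_to_tpm", "filter_expressed", "replicate_qc"]


@dataclass
class QCReport:
    """Replicate-level quality control summary.

    Attributes
    ----------
    pairwise_pearson
        Sample × sample Pearson correlation of log2(TPM+1) profiles;
        symmetric with unit diagonal.
    pca_scores
        Sample × k principal-component coordinates.
    variance_explained
        Fraction of total variance per component, non-increasing.
    """

    pairwise_pearson: pd.DataFrame
    pca_scores: pd.DataFrame
    variance_explained: np.ndarray


def counts_to_tpm(
    counts: ExpressionMatrix, models: Mapping[str, GeneModel]
) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene transcript lengths.

    Per sample: ``rate_g = count_g / length_kb_g`` and
    ``TPM_g = rate_g / sum(rates) * 1e6``, so every non-degenerate column
    sums to 1e6. An all-zero sample column stays all-zero with a warning.
    """
    if counts.unit != "raw_count":
        raise ValidationError(f"expected raw_count input, got {counts.unit}")
    missing = [g for g in counts.gene_ids if g not in models]
    if missing:
        raise ValidationError(f"genes without a length model: {missing[:10]}")
    lengths_kb = np.array([models[g].length for g in counts.gene_ids], dtype=float) / 1e3
    vals = counts.values.to_numpy(dtype=float)
    rates = vals / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample columns left as zero TPM: %s",
            [s for s, z in zip(counts.sample_ids, zero_cols) if z],
        )
    safe_totals = np.where(zero_cols, 1.0, totals)
    tpm = rates / safe_totals * 1e6
    tpm[:, zero_cols] = 0.0
    return ExpressionMatrix(
        values=pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns),
        layer=counts.layer,
        unit="TPM",
        condition_of_sample=dict(counts.condition_of_sample),
    )


def filter_expressed(
    tpm: ExpressionMatrix,
    rule: str = "any_replicate",
    threshold: float = 1.0,
    condition: str | None = None,
) -> list[str]:
    """Expressed-gene subset: TPM strictly above ``threshold``.

    ``any_replicate`` keeps a gene if any sample (of the given condition,
    or of all samples when ``condition`` is None) exceeds the threshold;
    ``mean`` uses the condition mean. Inequalities are strict, so a gene
    sitting exactly at the threshold is dropped.
    """
    if tpm.unit != "TPM":
        raise ValidationError(f"filter_expressed needs TPM input, got {tpm.unit}")
    if rule not in ("any_replicate", "mean"):
        raise ValidationError(f"unknown rule {rule!r}")
    sub = tpm.condition_values(condition) if condition is not None else tpm.values
    if rule == "any_replicate":
        keep = (sub > threshold).any(axis=1)
    else:
        keep = sub.mean(axis=1) > threshold
    return list(sub.index[keep])


def replicate_qc(tpm: ExpressionMatrix, k: int = 2) -> QCReport:
    """Pairwise Pearson correlation and PCA scores on log2(TPM+1).

    Genes are features, samples are observations; data are centered but not
    scaled. PC signs are fixed by making each component's largest-magnitude
    gene loading positive, so output is deterministic.
    """
    n_samples = len(tpm.sample_ids)
    if n_samples < 2:
        raise ValidationError("replicate_qc needs at least 2 samples")
    if k >= n_samples:
        raise ValidationError(f"k={k} must be < number of samples ({n_samples})")
    log_vals = np.log2(tpm.values.to_numpy(dtype=float) + 1.0)
    corr = np.corrcoef(log_vals.T)
    corr_df = pd.DataFrame(corr, index=tpm.sample_ids, columns=tpm.sample_ids)

    x = log_vals.T  # samples × genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(min(k, vt.shape[0])):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    var = s**2 / max(n_samples - 1, 1)
    total = var.sum()
    var_frac = var[:k] / total if total > 0 else np.zeros(k)
    score_df = pd.DataFrame(
        scores, index=tpm.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )
    return QCReport(
        pairwise_pearson=corr_df, pca_scores=score_df, variance_explained=var_frac
    )
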