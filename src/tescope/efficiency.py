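"""Translational efficiency (TE): the core per-gene statistic.

TE for a gene in one condition is the ratio of its mean translatome TPM to
its mean transcriptome TPM over that condition's replicates. Only genes
whose transcriptome TPM exceeds the expression threshold in at least one
replicate of the condition are eligible, which bounds the denominator away
from zero; the numerator gets no pseudocount, so TE = 0 is allowed.

TE changes between conditions are called up/down by fold change alone
(FC > 1.5 up, FC < 0.67 down), and TE values are binned as high (TE > 2),
low (TE < 0.5), or mid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, Thresholds, ValidationError

__all__ = ["compute_te", "te_change", "te_census", "TEChange"]


def _bin_te(te: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    out = np.full(te.shape, "mid", dtype=object)
    out[te > thresholds.te_high] = "high"
    out[te < thresholds.te_low] = "low"
    return out


def compute_te(
    translatome_tpm: ExpressionMatrix,
    transcriptome_tpm: ExpressionMatrix,
    condition: str,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Per-gene TE for one condition.

    Eligibility: transcriptome TPM strictly above ``expr_tpm_min`` in at
    least one replicate of the condition. Ineligible genes are absent from
    the output. Returns a DataFrame indexed by gene id with columns
    ``te`` and ``bin``.
    """
    for m, name in ((translatome_tpm, "translatome"), (transcriptome_tpm, "transcriptome")):
        # TE is a ratio of within-sample-normalized abundances; raw counts
        # would confound it with library size
        if m.unit == "raw_count":
            raise ValidationError(f"{name} matrix must be normalized (TPM), got raw_count")
    shared = translatome_tpm.values.index.intersection(transcriptome_tpm.values.index)
    tl = translatome_tpm.condition_values(condition).loc[shared]
    tx = transcriptome_tpm.condition_values(condition).loc[shared]
    eligible = (tx > thresholds.expr_tpm_min).any(axis=1)
    if not eligible.any():
        raise ValidationError(f"no eligible genes in condition {condition!r}")
    tl_mean = tl.loc[eligible].mean(axis=1)
    tx_mean = tx.loc[eligible].mean(axis=1)
    te = (tl_mean / tx_mean).to_numpy()
    return pd.DataFrame(
        {"te": te, "bin": _bin_te(te, thresholds)}, index=tl_mean.index
    )


@dataclass
class TEChange:
    """TE comparison between two conditions.

    ``records``: genes eligible in both conditions, indexed by gene id,
    with columns ``te_a, te_b, log2_te_fc, bin_a, bin_b, direction``.
    ``specific_a``/``specific_b``: genes eligible only in that condition.
    """

    records: pd.DataFrame
    specific_a: list[str]
    specific_b: list[str]


def te_change(
    te_table_a: pd.DataFrame, te_table_b: pd.DataFrame, thresholds: Thresholds
) -> TEChange:
    """TE fold change for genes eligible in both conditions.

    Direction: up iff TE_b/TE_a > fc_up, down iff < fc_down (fold change
    alone, no test). Genes eligible in only one condition are reported
    separately, not silently dropped.
    """
    shared = te_table_a.index.intersection(te_table_b.index)
    only_a = te_table_a.index.difference(te_table_b.index)
    only_b = te_table_b.index.difference(te_table_a.index)
    te_a = te_table_a.loc[shared, "te"].to_numpy()
    te_b = te_table_b.loc[shared, "te"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(te_a > 0, te_b / te_a, np.inf)
        log2fc = np.log2(fc)
    direction = np.full(len(shared), "unchanged", dtype=object)
    direction[fc > thresholds.fc_up] = "up"
    direction[fc < thresholds.fc_down] = "down"
    records = pd.DataFrame(
        {
            "te_a": te_a,
            "te_b": te_b,
            "log2_te_fc": log2fc,
            "bin_a": te_table_a.loc[shared, "bin"].to_numpy(),
            "bin_b": te_table_b.loc[shared, "bin"].to_numpy(),
            "direction": direction,
        },
        index=shared,
    )
    return TEChange(records=records, specific_a=list(only_a), specific_b=list(only_b))


def te_census(change: TEChange) -> dict[str, int]:
    """Deterministic counts over a TE comparison.

    high_a/high_b and low_a/low_b are bin counts per condition;
    up/down are TE-change direction counts; high_overlap is the number of
    genes high-TE in both conditions.
    """
    rec = change.records
    if rec.empty:
        raise ValidationError("te_census needs a non-empty TE record table")
    high_a = rec["bin_a"] == "high"
    high_b = rec["bin_b"] == "high"
    return {
        "high_a": int(high_a.sum()),
        "high_b": int(high_b.sum()),
        "low_a": int((rec["bin_a"] == "low").sum()),
        "low_b": int((rec["bin_b"] == "low").sum()),
        "up": int((rec["direction"] == "up").sum()),
        "down": int((rec["direction"] == "down").sum()),
        "specific_a": len(change.specific_a),
        "specific_b": len(change.specific_b),
        "high_overlap": int((high_a & high_b).sum()),
    }
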