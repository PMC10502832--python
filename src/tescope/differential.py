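"""Layer-wise differential expression and the four-class regulation partition.

Fold changes are computed on condition means of TPM with a small
pseudocount; significance comes from a two-sided Welch t-test on
log2(TPM+1), with no multiple-testing correction by default (the classic
volcano rule: raw p < alpha together with a fold-change bound). A
Benjamini–Hochberg option exists but is off by default.

The regulation classes combine translatome and transcriptome calls:

=====  ==================  ====================
class  translatome          transcriptome
=====  ==================  ====================
I      up                   up
II     down                 unchanged
III    up                   unchanged
IV     down                 down
none   any other combination
=====  ==================  ====================

Classes II and III capture genes whose translation changes while
transcription stays constant — the dominant mode in transcriptionally
quiescent cells such as fully grown oocytes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, Thresholds, ValidationError

__all__ = [
    "differential_expression",
    "classify_regulation",
    "cross_layer_correlation",
    "proteome_direction",
    "FC_PSEUDOCOUNT",
]

#: Pseudocount (TPM) added to both condition means before taking the ratio.
FC_PSEUDOCOUNT = 0.01

REGULATION_CLASSES = ("I", "II", "III", "IV", "none")


def _direction(fc: np.ndarray, p: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    out = np.full(fc.shape, "unchanged", dtype=object)
    out[(fc > thresholds.fc_up) & (p < thresholds.alpha)] = "up"
    out[(fc < thresholds.fc_down) & (p < thresholds.alpha)] = "down"
    return out


def differential_expression(
    tpm: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thresholds: Thresholds,
    genes: Sequence[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and Welch t-test between two sample groups.

    FC = (mean_B + eps) / (mean_A + eps) on TPM condition means with
    eps = 0.01 TPM; p from a two-sided Welch (unequal-variance) t-test on
    log2(TPM+1). Direction is 'up' iff FC > fc_up and p < alpha, 'down'
    iff FC < fc_down and p < alpha, else 'unchanged'.

    Returns a DataFrame indexed by gene id with columns
    ``layer, log2fc, p_value, direction`` (plus ``q_value`` when
    ``fdr=True``, in which case direction uses q).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >=2 replicates")
    for s in group_a + group_b:
        if s not in tpm.values.columns:
            raise ValidationError(f"sample {s!r} not in matrix")
    sub = tpm.values.loc[list(genes)] if genes is not None else tpm.values
    a = sub[group_a].to_numpy(dtype=float)
    b = sub[group_b].to_numpy(dtype=float)

    fc = (b.mean(axis=1) + FC_PSEUDOCOUNT) / (a.mean(axis=1) + FC_PSEUDOCOUNT)
    log_a, log_b = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    # Zero variance in both groups with equal means gives NaN; no evidence
    # of change, so p := 1.
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame(
        {
            "layer": tpm.layer,
            "log2fc": np.log2(fc),
            "p_value": p,
        },
        index=sub.index,
    )
    if fdr:
        out["q_value"] = multipletests(p, method="fdr_bh")[1]
        out["direction"] = _direction(fc, out["q_value"].to_numpy(), thresholds)
    else:
        out["direction"] = _direction(fc, p, thresholds)
    return out


def classify_regulation(
    de_translatome: pd.DataFrame, de_transcriptome: pd.DataFrame
) -> pd.DataFrame:
    """Assign each gene a translation/transcription regulation class.

    Genes missing from either layer get class 'none'. The classes are
    mutually exclusive and collectively exhaust the union of both tables'
    gene universes.
    """
    universe = de_translatome.index.union(de_transcriptome.index)
    tl = de_translatome["direction"].reindex(universe, fill_value="absent")
    tx = de_transcriptome["direction"].reindex(universe, fill_value="absent")
    klass = pd.Series("none", index=universe, dtype=object, name="klass")
    klass[(tl == "up") & (tx == "up")] = "I"
    klass[(tl == "down") & (tx == "unchanged")] = "II"
    klass[(tl == "up") & (tx == "unchanged")] = "III"
    klass[(tl == "down") & (tx == "down")] = "IV"
    return klass.to_frame()


def cross_layer_correlation(
    fc_layer1: Mapping[str, float] | pd.Series,
    fc_layer2: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between two per-gene log2 fold-change vectors.

    Vectors are intersected on gene id; returns (r, two-sided p).
    """
    s1 = pd.Series(fc_layer1, dtype=float)
    s2 = pd.Series(fc_layer2, dtype=float)
    shared = s1.index.intersection(s2.index)
    if len(shared) < 3:
        raise ValidationError("need >=3 shared genes for correlation")
    x, y = s1[shared].to_numpy(), s2[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in a fold-change vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def proteome_direction(
    fold_changes: Mapping[str, float] | pd.Series, thresholds: Thresholds
) -> pd.DataFrame:
    """Direction calls for a precomputed proteome fold-change table.

    Single-replicate proteomics gets no statistical test: up means
    FC > proteome_fc_up, down means FC < proteome_fc_down.
    """
    fc = pd.Series(fold_changes, dtype=float)
    direction = np.full(len(fc), "unchanged", dtype=object)
    direction[fc.to_numpy() > thresholds.proteome_fc_up] = "up"
    direction[fc.to_numpy() < thresholds.proteome_fc_down] = "down"
    return pd.DataFrame(
        {"layer": "proteome", "log2fc": np.log2(fc), "direction": direction},
        index=fc.index,
    )
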