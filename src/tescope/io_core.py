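"""Shared domain types, file formats, thresholds, and configuration.

Every other stage consumes only the validated containers defined here
(:class:`ExpressionMatrix`, :class:`GeneModel` tables, :class:`GeneSet`,
:class:`Thresholds`); no downstream stage reads files directly.

Tables are tab-separated UTF-8 with a decimal point and no thousands
separators. Gene identifiers are opaque, case-sensitive strings everywhere
except the explicit cross-species matching mode in :mod:`tescope.prioritize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tescope")

LAYERS = ("translatome", "transcriptome", "proteome")
UNITS = ("raw_count", "TPM", "abundance")

#: Relative tolerance for the per-sample TPM column-sum invariant.
TPM_SUM_RTOL = 1e-6

__all__ = [
    "Thresholds",
    "ExpressionMatrix",
    "GeneModel",
    "GeneSet",
    "read_expression_table",
    "write_expression_table",
    "read_gene_models",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "load_config",
]


class ValidationError(ValueError):
    """An input violated a container invariant."""


@dataclass(frozen=True)
class Thresholds:
    """All analysis cutoffs, threaded through every stage.

    No stage hard-codes a cutoff: the same fold-change and TE bounds are
    reused across expression filtering, differential calls, TE binning and
    the candidate cascade, mirroring how a single rule set governs an
    entire study.

    Parameters
    ----------
    expr_tpm_min
        Expressed-gene filter: a gene must exceed this TPM (strictly) in at
        least one replicate (or in the condition mean, depending on rule).
    fc_up, fc_down
        Fold-change bounds for up/down calls on expression and TE
        (ratio scale; 1.5 and 0.67 by default).
    alpha
        Raw p-value cutoff used together with the fold-change bounds.
    te_high, te_low
        TE bin edges: high-TE means TE > ``te_high``, low-TE means
        TE < ``te_low``.
    papcpe_window
        Maximum gap (nt) between a CPE and a PAS for the CPE to count as a
        papCPE.
    concordant_log2fc
        Strict upper bound on translational log2 fold change used by the
        final cascade stage (−0.58 ≈ log2(0.67)).
    proteome_fc_up, proteome_fc_down
        Fold-change bounds for single-replicate proteome tables, where no
        statistical test is attempted.
    """

    expr_tpm_min: float = 1.0
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    te_high: float = 2.0
    te_low: float = 0.5
    papcpe_window: int = 100
    concordant_log2fc: float = -0.58
    proteome_fc_up: float = 1.2
    proteome_fc_down: float = 0.83

    def __post_init__(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValidationError(
                f"need fc_down < 1 < fc_up, got {self.fc_down}, {self.fc_up}"
            )
        if not (self.te_low < 1.0 < self.te_high):
            raise ValidationError(
                f"need te_low < 1 < te_high, got {self.te_low}, {self.te_high}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.papcpe_window <= 0:
            raise ValidationError("papcpe_window must be positive")
        if not (self.proteome_fc_down < 1.0 < self.proteome_fc_up):
            raise ValidationError("need proteome_fc_down < 1 < proteome_fc_up")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values for one layer.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``condition_of_sample`` maps every sample to its condition label.
    """

    values: pd.DataFrame
    layer: str
    unit: str
    condition_of_sample: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; one of {LAYERS}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; one of {UNITS}")
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite")
        if (vals < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.condition_of_sample]
        if missing:
            raise ValidationError(f"samples without condition label: {missing}")
        if self.unit == "TPM":
            sums = vals.sum(axis=0)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1e6, rtol=TPM_SUM_RTOL):
                raise ValidationError(
                    "TPM columns must sum to 1e6 (rtol 1e-6); "
                    f"got sums {sums.tolist()}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        out = [s for s in self.values.columns if self.condition_of_sample[s] == condition]
        if not out:
            raise ValidationError(f"no samples with condition {condition!r}")
        return out

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]


@dataclass(frozen=True)
class GeneModel:
    """Transcript model: length in nt (for TPM) and optional 3'UTR sequence."""

    gene_id: str
    length: int
    utr3_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.gene_id}: length must be >= 1")
        if self.utr3_sequence is not None:
            bad = set(self.utr3_sequence) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"{self.gene_id}: 3'UTR has characters outside ACGTN: {sorted(bad)}"
                )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    layer: str,
    unit: str,
    condition_map: Mapping[str, str],
) -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample ids, first column = gene ids).

    Raises a parse error naming the offending row/column for non-numeric
    cells and a validation error for duplicated gene ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValidationError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}: "
                    f"{df.loc[row, col]!r}"
                ) from None
        raise
    return ExpressionMatrix(
        values=values, layer=layer, unit=unit, condition_of_sample=dict(condition_map)
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with 6 significant digits (round-trips bit-exactly)."""
    matrix.values.to_csv(Path(path), sep="\t", float_format="%.6g", index_label="gene_id")


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read a two-column TSV (gene_id, length) of gene models."""
    df = pd.read_csv(Path(path), sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns gene_id, length")
    gene_col, len_col = df.columns[0], df.columns[1]
    models: dict[str, GeneModel] = {}
    for gid, length in zip(df[gene_col].astype(str), df[len_col].astype(int)):
        if gid in models:
            raise ValidationError(f"{path}: duplicate gene id {gid!r}")
        models[gid] = GeneModel(gene_id=gid, length=int(length))
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(models), "length": [m.length for m in models.values()]}
    )
    df.to_csv(Path(path), sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets (name, description, members; tab-separated).

    The description field is discarded. Duplicate members within a line are
    deduplicated with a logged warning; a line with fewer than three fields
    is a parse error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, members = parts[0], parts[2:]
            if len(set(members)) < len(members):
                logger.warning(
                    "%s:%d: gene set %r has duplicate members; deduplicating",
                    path, lineno, name,
                )
            sets.append(GeneSet.from_iterable(name, members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA of 3'UTR sequences; headers (first word) are gene ids."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_THRESHOLD_KEYS = {f.name for f in fields(Thresholds)}


def load_config(path: str | Path | None) -> tuple[Thresholds, dict]:
    """Load a YAML config into (Thresholds, run plan).

    Threshold keys override the defaults; everything else is returned as the
    run plan (input paths, stage selection). Unknown scalar keys at the top
    level that look like misspelled thresholds are rejected. The resolved
    thresholds are echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
    thresh_kwargs = {}
    plan: dict = {}
    known_plan_keys = {
        "inputs", "stages", "out_dir", "seed", "conditions", "log_level",
        "filter_rule", "gsea", "length_source", "analyses", "annotations",
        "cascade",
    }
    for key, value in raw.items():
        if key in _THRESHOLD_KEYS:
            thresh_kwargs[key] = value
        elif key in known_plan_keys:
            plan[key] = value
        else:
            raise ValidationError(f"unknown config key {key!r}")
    thresholds = Thresholds(**thresh_kwargs)
    logger.info("resolved thresholds: %s", thresholds)
    return thresholds, plan
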