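"""End-to-end orchestration: quantify → differential → efficiency →
annotate → stratify → prioritize from one YAML config.

The config names one or more *analyses* (each a two-condition contrast
with its own count tables), shared annotation resources (m6A GMT, RIP
replicate GMT, 3'UTR FASTA, optional hallmark GMT), and optionally a
``cascade`` entry naming the two analyses whose TE comparisons feed the
candidate cascade. The plan is validated before any computation starts
(fail-fast), every stage writes TSV/JSON under the output directory, and
the manifest records input checksums, resolved thresholds and the seed.
JSON floats are fixed at 10 significant digits, so identical inputs and
seed reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_utrs, rip_consensus, tag_genes
from .differential import classify_regulation, cross_layer_correlation, differential_expression
from .efficiency import compute_te, te_census, te_change
from .io_core import (
    Thresholds,
    ValidationError,
    load_config,
    read_expression_table,
    read_fasta,
    read_gene_models,
    read_gmt,
)
from .prioritize import candidate_cascade
from .quantify import counts_to_tpm, filter_expressed, replicate_qc
from .stratify import compare_four_groups, compare_two_groups, preranked_gsea

logger = logging.getLogger("tescope")

__all__ = ["RunManifest", "run_pipeline", "stable_json"]

STAGES = ("quantify", "differential", "efficiency", "annotate", "stratify", "prioritize")


def _round_floats(obj: Any) -> Any:
    """Round every float to 10 significant digits for stable JSON output."""
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def stable_json(obj: Any) -> str:
    return json.dumps(_round_floats(obj), sort_keys=True, indent=1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    inputs: dict[str, str]          # path -> sha256
    thresholds: Thresholds
    seed: int
    outputs: list[str]
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "thresholds": vars(self.thresholds).copy(),
            "seed": self.seed,
            "outputs": sorted(self.outputs),
            "version": self.version,
        }


def _validate_plan(plan: Mapping[str, Any]) -> tuple[dict, dict, list[str], list[str]]:
    """Fail-fast validation of the run plan; returns
    (analyses, annotations, stages, cascade_pair)."""
    analyses = plan.get("analyses")
    if not analyses:
        raise ValidationError("config must define at least one analysis under 'analyses'")
    annotations = plan.get("annotations") or {}
    stages = list(plan.get("stages") or STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages {unknown}; valid: {list(STAGES)}")

    for name, spec in analyses.items():
        if "transcriptome_counts" not in spec:
            raise ValidationError(f"analysis {name!r}: transcriptome_counts is required")
        if "lengths" not in spec:
            raise ValidationError(f"analysis {name!r}: lengths table is required")
        conds = spec.get("conditions")
        if not conds or len(conds) != 2:
            raise ValidationError(f"analysis {name!r}: exactly two conditions required")
        for key in ("translatome_counts", "transcriptome_counts", "lengths", "proteome_fc"):
            if key in spec and not Path(spec[key]).exists():
                raise ValidationError(f"analysis {name!r}: missing input file {spec[key]}")

    for key, path in annotations.items():
        if not Path(path).exists():
            raise ValidationError(f"annotation input {key!r} missing: {path}")

    if "stratify" in stages and "utr_fasta" not in annotations and "m6a_gmt" not in annotations:
        raise ValidationError(
            "stratify stage requested but neither utr_fasta nor m6a_gmt provided"
        )
    cascade_pair = list(plan.get("cascade") or [])
    if "prioritize" in stages and cascade_pair:
        if len(cascade_pair) != 2:
            raise ValidationError("cascade must name exactly two analyses")
        for name in cascade_pair:
            if name not in analyses:
                raise ValidationError(f"cascade references unknown analysis {name!r}")
            if "translatome_counts" not in analyses[name]:
                raise ValidationError(
                    f"cascade analysis {name!r} needs a translatome table"
                )
        if "rip_gmt" not in annotations or "m6a_gmt" not in annotations:
            raise ValidationError("cascade requires m6a_gmt and rip_gmt annotations")
    return dict(analyses), dict(annotations), stages, cascade_pair


def _write_json(obj: Any, path: Path, outputs: list[str]) -> None:
    path.write_text(stable_json(obj) + "\n", encoding="utf-8")
    outputs.append(str(path))


def _write_tsv(df: pd.DataFrame, path: Path, outputs: list[str], **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kwargs)
    outputs.append(str(path))


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Run all requested stages for every configured analysis.

    Returns the manifest; the report bundle is written under ``out_dir``
    with one directory per analysis plus ``manifest.json``.
    """
    thresholds, plan = load_config(config_path)
    analyses, annotations, stages, cascade_pair = _validate_plan(plan)
    seed = int(plan.get("seed", 0))
    out_root = Path(out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    inputs: dict[str, str] = {str(Path(config_path)): _sha256(Path(config_path))}
    outputs: list[str] = []

    m6a_set = rip_sets = utrs = hallmark = None
    if "m6a_gmt" in annotations:
        sets = read_gmt(annotations["m6a_gmt"])
        m6a_set = sets[0]
        inputs[annotations["m6a_gmt"]] = _sha256(Path(annotations["m6a_gmt"]))
    if "rip_gmt" in annotations:
        rip_sets = read_gmt(annotations["rip_gmt"])
        inputs[annotations["rip_gmt"]] = _sha256(Path(annotations["rip_gmt"]))
    if "utr_fasta" in annotations:
        utrs = read_fasta(annotations["utr_fasta"])
        inputs[annotations["utr_fasta"]] = _sha256(Path(annotations["utr_fasta"]))
    if "hallmark_gmt" in annotations:
        hallmark = read_gmt(annotations["hallmark_gmt"])
        inputs[annotations["hallmark_gmt"]] = _sha256(Path(annotations["hallmark_gmt"]))

    rip_consensus_set = rip_consensus(rip_sets) if rip_sets else None
    utr_annotations = annotate_utrs(utrs, window=thresholds.papcpe_window) if utrs else None

    te_changes: dict[str, Any] = {}
    transl_fcs: dict[str, pd.Series] = {}

    for name, spec in analyses.items():
        adir = out_root / name
        adir.mkdir(exist_ok=True)
        cond_a, cond_b = spec["conditions"]
        models = read_gene_models(spec["lengths"])
        inputs[spec["lengths"]] = _sha256(Path(spec["lengths"]))
        cond_map: dict[str, str] = {}

        layers: dict[str, Any] = {}
        for layer, key in (("transcriptome", "transcriptome_counts"),
                           ("translatome", "translatome_counts")):
            if key not in spec:
                continue
            path = Path(spec[key])
            inputs[str(path)] = _sha256(path)
            header = pd.read_csv(path, sep="\t", nrows=0, index_col=0)
            for s in header.columns:
                cond_map[s] = cond_a if s.startswith(cond_a) else cond_b
            counts = read_expression_table(path, layer, "raw_count", cond_map)
            layers[layer] = counts_to_tpm(counts, models)

        if "translatome" not in layers:
            logger.warning("analysis %s: no translatome; TE stages skipped", name)

        if "quantify" in stages:
            for layer, tpm in layers.items():
                _write_tsv(tpm.values, adir / f"{layer}_tpm.tsv", outputs,
                           index_label="gene_id")
                qc = replicate_qc(tpm, k=2)
                _write_json(
                    {
                        "pairwise_pearson": qc.pairwise_pearson.to_dict(),
                        "variance_explained": qc.variance_explained,
                        "pca_scores": qc.pca_scores.to_dict(),
                    },
                    adir / f"{layer}_qc.json",
                    outputs,
                )

        de_tables: dict[str, pd.DataFrame] = {}
        if "differential" in stages:
            for layer, tpm in layers.items():
                expressed = sorted(
                    set(filter_expressed(tpm, "any_replicate", thresholds.expr_tpm_min, cond_a))
                    | set(filter_expressed(tpm, "any_replicate", thresholds.expr_tpm_min, cond_b))
                )
                de = differential_expression(
                    tpm, tpm.samples_of(cond_a), tpm.samples_of(cond_b),
                    thresholds, genes=expressed,
                )
                de_tables[layer] = de
                _write_tsv(de, adir / f"de_{layer}.tsv", outputs, index_label="gene_id")
            if "translatome" in de_tables and "transcriptome" in de_tables:
                classes = classify_regulation(
                    de_tables["translatome"], de_tables["transcriptome"]
                )
                counts = classes["klass"].value_counts().to_dict()
                shared = de_tables["translatome"].index.intersection(
                    de_tables["transcriptome"].index
                )
                r, p = cross_layer_correlation(
                    de_tables["translatome"].loc[shared, "log2fc"],
                    de_tables["transcriptome"].loc[shared, "log2fc"],
                )
                _write_tsv(classes, adir / "regulation_classes.tsv", outputs,
                           index_label="gene_id")
                _write_json(
                    {"class_counts": counts, "cross_layer_pearson_r": r,
                     "cross_layer_pearson_p": p},
                    adir / "regulation_summary.json", outputs,
                )
            if "translatome" in de_tables:
                transl_fcs[name] = de_tables["translatome"]["log2fc"]

        if "efficiency" in stages and "translatome" in layers:
            te_a = compute_te(layers["translatome"], layers["transcriptome"], cond_a, thresholds)
            te_b = compute_te(layers["translatome"], layers["transcriptome"], cond_b, thresholds)
            change = te_change(te_a, te_b, thresholds)
            te_changes[name] = change
            _write_tsv(change.records, adir / "te_change.tsv", outputs,
                       index_label="gene_id")
            _write_json(te_census(change), adir / "te_census.json", outputs)

        if "annotate" in stages and (m6a_set or rip_consensus_set or utr_annotations):
            universe = layers["transcriptome"].gene_ids
            features = tag_genes(universe, m6a_set, utr_annotations, rip_consensus_set)
            _write_tsv(features, adir / "features.tsv", outputs)

        if "stratify" in stages and name in te_changes:
            values = te_changes[name].records["log2_te_fc"]
            values = values[np.isfinite(values)]
            strat: dict[str, Any] = {}
            features = tag_genes(list(values.index), m6a_set, utr_annotations,
                                 rip_consensus_set)
            if m6a_set is not None:
                s = compare_two_groups(values, features["m6a"],
                                       labels=("non_m6a", "m6a"))
                strat["m6a_vs_non_m6a"] = {
                    "p": s.p_value, "mean": s.mean_per_group, "n": s.n_per_group}
            if utr_annotations is not None:
                s = compare_two_groups(values, features["papcpe"],
                                       labels=("non_papcpe", "papcpe"))
                strat["papcpe_vs_non_papcpe"] = {
                    "p": s.p_value, "mean": s.mean_per_group, "n": s.n_per_group}
            if m6a_set is not None and utr_annotations is not None:
                try:
                    s4 = compare_four_groups(values, features["m6a"],
                                             features["papcpe"], names=("m6a", "papcpe"))
                    strat["m6a_x_papcpe"] = {
                        "anova_p": s4.p_value,
                        "pairwise": s4.pairwise.to_dict(orient="records"),
                        "mean": s4.mean_per_group,
                    }
                except ValidationError as exc:
                    strat["m6a_x_papcpe"] = {"skipped": str(exc)}
            if hallmark and name in transl_fcs:
                gsea_out = []
                for gs in hallmark:
                    present = gs.members & set(transl_fcs[name].index)
                    if present and len(present) < len(transl_fcs[name]):
                        res = preranked_gsea(transl_fcs[name], gs, seed=seed)
                        gsea_out.append({"set": gs.name, "es": res.es,
                                         "nes": res.nes, "p": res.p})
                strat["gsea_translatome"] = gsea_out
            _write_json(strat, adir / "stratified_stats.json", outputs)

    if "prioritize" in stages and len(cascade_pair) == 2:
        a, b = cascade_pair
        report = candidate_cascade(
            te_changes[a], te_changes[b], m6a_set, rip_consensus_set,
            transl_fcs[a], transl_fcs[b], thresholds,
        )
        _write_json(report.to_dict(), out_root / "cascade.json", outputs)

    manifest = RunManifest(inputs=inputs, thresholds=thresholds, seed=seed,
                           outputs=[str(Path(o).relative_to(out_root)) for o in outputs])
    (out_root / "manifest.json").write_text(
        stable_json(manifest.to_dict()) + "\n", encoding="utf-8"
    )
    return manifest
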