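"""Synthetic paired translatome/transcriptome cohorts with ground truth.

The generator emulates the statistical structure the analysis assumes in a
transcriptionally quiescent cell such as a fully grown oocyte:

* transcription is held constant — per-gene transcriptome means are
  identical across conditions;
* translation changes — the translatome mean is the transcriptome mean
  times a per-gene true TE, and aging multiplies the true TE of an
  "affected" subset by ``2**aging_te_log2_shift``;
* the affected subset is concentrated where the effect is observed in
  aged oocytes: m6A-flagged genes whose baseline TE is high (> te_high);
* counts are negative binomial with gene-length-weighted means scaled to a
  library size, so TPM normalization round-trips sensibly for a
  length-biased full-length protocol;
* RIP replicate target lists are noisy observations of the m6A gene set
  (per-replicate sensitivity and false-positive rate);
* 3'UTR sequences are synthesized from per-gene CPE/papCPE flags with
  motif-scrubbed backgrounds, so re-annotating them recovers exactly the
  planted flags.

Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import call_papcpe, scan_motifs
from .io_core import ExpressionMatrix, GeneModel, GeneSet, ValidationError

__all__ = ["SimParams", "Cohort", "generate_cohort", "generate_utr", "write_cohort"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults define the reference study conditions.

    ``mean_log2_expression`` ~ Normal(5, 2) gives TPM-scale baseline
    abundances; ``baseline_log2_te`` ~ Normal(0, 1) gives baseline TEs
    centered at 1 with a realistic high-TE tail. 55% of genes carry the
    m6A flag, and 80% of m6A & high-TE genes receive a −1 log2 TE shift
    with aging. RIP replicate lists observe m6A genes at 80% sensitivity
    with a 5% false-positive rate.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    conditions: tuple[str, str] = ("young", "aged")
    mean_log2_expression: tuple[float, float] = (5.0, 2.0)
    nb_dispersion: float = 0.1
    baseline_log2_te: tuple[float, float] = (0.0, 1.0)
    frac_m6a: float = 0.55
    frac_high_te_affected: float = 0.8
    aging_te_log2_shift: float = -1.0
    frac_cpe: float = 0.4
    frac_papcpe_given_cpe: float = 0.5
    rip_n_replicates: int = 3
    rip_sensitivity: float = 0.8
    rip_false_positive: float = 0.05
    utr_length_range: tuple[int, int] = (200, 1500)
    gene_length_range: tuple[int, int] = (500, 3000)
    library_size: float = 1e6
    te_high: float = 2.0
    papcpe_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_m6a": self.frac_m6a,
            "frac_high_te_affected": self.frac_high_te_affected,
            "frac_cpe": self.frac_cpe,
            "frac_papcpe_given_cpe": self.frac_papcpe_given_cpe,
            "rip_sensitivity": self.rip_sensitivity,
            "rip_false_positive": self.rip_false_positive,
        }
        for name, val in fracs.items():
            if not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {val}")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if len(self.conditions) != 2:
            raise ValidationError("exactly two conditions required")


@dataclass
class Cohort:
    """A generated paired-omics cohort plus its ground truth."""

    translatome_counts: ExpressionMatrix
    transcriptome_counts: ExpressionMatrix
    models: dict[str, GeneModel]
    utr_sequences: dict[str, str]
    m6a_set: GeneSet
    rip_replicates: list[GeneSet]
    truth: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.clip(mean, 0.0, None)
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    p = np.clip(p, 1e-12, 1.0)
    return rng.negative_binomial(size_param, p)


def _layer_counts(
    rng: np.random.Generator,
    abundance: np.ndarray,  # genes, TPM-scale relative abundance
    lengths_kb: np.ndarray,
    n_samples: int,
    params: SimParams,
) -> np.ndarray:
    # Expected read counts are length-biased: a transcript contributes
    # fragments in proportion to abundance x length.
    weights = abundance * lengths_kb
    frac = weights / weights.sum()
    mu = frac * params.library_size
    return np.column_stack(
        [_nb_draw(rng, mu, params.nb_dispersion) for _ in range(n_samples)]
    )


def generate_utr(
    cpe: bool,
    papcpe: bool,
    length: int,
    rng: np.random.Generator | int,
    window: int = 100,
    max_tries: int = 200,
) -> str:
    """Synthesize a 3'UTR honoring the given CPE/papCPE flags.

    Backgrounds are uniform ACGT with any accidental CPE/PAS occurrence
    scrubbed by redrawing, then the requested motifs are planted:

    * a PAS is planted near the 3' end (the biological convention) unless
      that would violate a requested cpe-without-papcpe constraint in a
      short UTR, in which case the PAS is omitted;
    * if ``cpe``, at least one CPE is planted — within ``window`` nt of
      the PAS when ``papcpe``, and more than ``window`` nt away otherwise.

    The final sequence is re-annotated and rejected (redrawn) on any
    mismatch, so the round trip through the annotator is exact by
    construction. Backgrounds are therefore not i.i.d. uniform.
    """
    if papcpe and not cpe:
        raise ValidationError("papcpe requires cpe")
    if length < 60:
        raise ValidationError(f"UTR length must be >= 60, got {length}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    bases = np.array(list("ACGT"))
    motif_len = 6
    pas_motif = "AATAAA"
    cpe_motif = "TTTTAT"

    for _ in range(max_tries):
        seq = rng.choice(bases, size=length)
        # scrub accidental motif occurrences from the background
        for _ in range(50):
            hits = scan_motifs("bg", "".join(seq))
            if not hits:
                break
            for h in hits:
                seq[h.start : h.end] = rng.choice(bases, size=h.end - h.start)
        else:
            continue

        # plant PAS near the 3' end where constraints allow
        pas_start: int | None = None
        if cpe and not papcpe:
            # CPE must sit > window nt from any PAS; omit the PAS if the
            # UTR is too short to fit both.
            if length >= motif_len + window + 1 + motif_len + 10:
                pas_start = length - motif_len - int(rng.integers(0, 10))
                pas_start = min(pas_start, length - motif_len)
        else:
            pas_start = length - motif_len - int(rng.integers(0, 10))
            pas_start = min(pas_start, length - motif_len)
        if pas_start is not None:
            seq[pas_start : pas_start + motif_len] = list(pas_motif)

        if cpe:
            if papcpe:
                assert pas_start is not None
                gap = int(rng.integers(0, min(window, pas_start - motif_len) + 1))
                cpe_end = pas_start - gap
                cpe_start = cpe_end - motif_len
            elif pas_start is not None:
                max_end = pas_start - window - 1
                cpe_start = int(rng.integers(0, max_end - motif_len + 1))
            else:
                cpe_start = int(rng.integers(0, length - motif_len + 1))
            if cpe_start < 0:
                continue
            seq[cpe_start : cpe_start + motif_len] = list(cpe_motif)

        candidate = "".join(seq)
        ann = call_papcpe(scan_motifs("utr", candidate), window=window)
        if ann.has_cpe == cpe and ann.has_papcpe == papcpe:
            return candidate
    raise ValidationError(
        f"could not honor flags cpe={cpe}, papcpe={papcpe} at length {length}"
    )


def generate_cohort(
    params: SimParams,
    with_utrs: bool = True,
    shared_truth: pd.DataFrame | None = None,
) -> Cohort:
    """Generate a full paired cohort from one parameter set.

    Returns raw-count matrices for both layers, gene models, 3'UTR
    sequences (unless ``with_utrs=False``), the m6A gene set, per-replicate
    RIP target sets, and a per-gene ground-truth table with columns
    ``mean_expression, te_young, te_aged, m6a, cpe, papcpe, rip_target,
    affected``.

    Passing ``shared_truth`` (the truth table of a previous cohort) reuses
    that cohort's per-gene baselines and feature flags and redraws only the
    affected subset, the counts and the RIP noise. This models a second
    perturbation of the *same* biological system — e.g. an m6A-reader
    knockdown alongside aging — where both contrasts suppress translation
    of overlapping subsets of the m6A-marked high-TE genes.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    width = len(str(n))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(n)]

    lengths = rng.integers(
        params.gene_length_range[0], params.gene_length_range[1] + 1, size=n
    )
    lengths_kb = lengths / 1e3
    models = {
        g: GeneModel(gene_id=g, length=int(l)) for g, l in zip(gene_ids, lengths)
    }

    if shared_truth is not None:
        if len(shared_truth) != n:
            raise ValidationError(
                f"shared_truth has {len(shared_truth)} genes, params say {n}"
            )
        gene_ids = list(shared_truth.index)
        expression = shared_truth["mean_expression"].to_numpy(dtype=float)
        te_young = shared_truth["te_young"].to_numpy(dtype=float)
        m6a = shared_truth["m6a"].to_numpy(dtype=bool)
        cpe = shared_truth["cpe"].to_numpy(dtype=bool)
        papcpe = shared_truth["papcpe"].to_numpy(dtype=bool)
    else:
        mu_e, sd_e = params.mean_log2_expression
        expression = 2.0 ** rng.normal(mu_e, sd_e, size=n)
        mu_t, sd_t = params.baseline_log2_te
        te_young = 2.0 ** rng.normal(mu_t, sd_t, size=n)
        m6a = rng.random(n) < params.frac_m6a
        cpe = rng.random(n) < params.frac_cpe
        papcpe = cpe & (rng.random(n) < params.frac_papcpe_given_cpe)

    high_te = te_young > params.te_high
    affected = m6a & high_te & (rng.random(n) < params.frac_high_te_affected)
    te_aged = np.where(affected, te_young * 2.0**params.aging_te_log2_shift, te_young)

    cond_a, cond_b = params.conditions
    te_by_cond = {cond_a: te_young, cond_b: te_aged}
    sample_ids: list[str] = []
    condition_map: dict[str, str] = {}
    tx_cols, tl_cols = [], []
    for cond in params.conditions:
        for rep in range(1, params.n_replicates + 1):
            sid = f"{cond}_{rep}"
            sample_ids.append(sid)
            condition_map[sid] = cond
            tx_cols.append(_layer_counts(rng, expression, lengths_kb, 1, params)[:, 0])
            tl_cols.append(
                _layer_counts(rng, expression * te_by_cond[cond], lengths_kb, 1, params)[:, 0]
            )

    def _matrix(cols: list[np.ndarray], layer: str) -> ExpressionMatrix:
        return ExpressionMatrix(
            values=pd.DataFrame(
                np.column_stack(cols).astype(float), index=gene_ids, columns=sample_ids
            ),
            layer=layer,
            unit="raw_count",
            condition_of_sample=dict(condition_map),
        )

    transcriptome = _matrix(tx_cols, "transcriptome")
    translatome = _matrix(tl_cols, "translatome")

    rip_replicates = []
    for r in range(1, params.rip_n_replicates + 1):
        detect = np.where(
            m6a,
            rng.random(n) < params.rip_sensitivity,
            rng.random(n) < params.rip_false_positive,
        )
        rip_replicates.append(
            GeneSet.from_iterable(f"rip_rep{r}", np.array(gene_ids)[detect])
        )
    m6a_set = GeneSet.from_iterable("m6a", np.array(gene_ids)[m6a])

    utrs: dict[str, str] = {}
    if with_utrs:
        lo, hi = params.utr_length_range
        utr_lengths = rng.integers(lo, hi + 1, size=n)
        for g, c, p, ul in zip(gene_ids, cpe, papcpe, utr_lengths):
            utrs[g] = generate_utr(
                bool(c), bool(p), int(ul), rng, window=params.papcpe_window
            )

    truth = pd.DataFrame(
        {
            "mean_expression": expression,
            "te_young": te_young,
            "te_aged": te_aged,
            "m6a": m6a,
            "cpe": cpe,
            "papcpe": papcpe,
            "rip_target": m6a,  # true reader targets are the m6A-marked genes
            "affected": affected,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return Cohort(
        translatome_counts=translatome,
        transcriptome_counts=transcriptome,
        models=models,
        utr_sequences=utrs,
        m6a_set=m6a_set,
        rip_replicates=rip_replicates,
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk: counts TSVs, models TSV, UTR FASTA, GMT
    files (m6A set, RIP replicates), and the truth table."""
    from pathlib import Path

    from .io_core import write_expression_table, write_fasta, write_gene_models, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(cohort.translatome_counts, out / "translatome_counts.tsv")
    write_expression_table(cohort.transcriptome_counts, out / "transcriptome_counts.tsv")
    write_gene_models(cohort.models, out / "gene_models.tsv")
    if cohort.utr_sequences:
        write_fasta(cohort.utr_sequences, out / "utr3.fasta")
    write_gmt([cohort.m6a_set], out / "m6a.gmt")
    write_gmt(cohort.rip_replicates, out / "rip_replicates.gmt")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", float_format="%.6g")
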