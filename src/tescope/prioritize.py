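"""Target prioritization: the staged candidate cascade and overlap analyses.

The cascade narrows the gene universe to high-confidence, m6A-dependent
reader targets in three stages:

1. genes whose TE changed (direction != unchanged) in *both* comparisons
   (e.g. aged-vs-young and reader-knockdown-vs-control), intersected with
   the m6A gene set and the RIP consensus target set;
2. the stage-1 genes whose TE is *down* in both comparisons (the
   stage-2/stage-1 ratio is reported as the concordance fraction);
3. the stage-2 genes whose translational log2 fold change is strictly
   below ``concordant_log2fc`` (default −0.58, i.e. FC < 0.67) in both
   comparisons.

Each stage's members are a subset of the previous stage's, so relaxing the
final threshold toward 0 can only grow the candidate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .efficiency import TEChange
from .io_core import GeneSet, Thresholds, ValidationError

logger = logging.getLogger("tescope")

__all__ = [
    "CascadeStage",
    "CascadeReport",
    "OverlapSummary",
    "candidate_cascade",
    "overlap_analysis",
    "concordance_scatter",
]


@dataclass
class CascadeStage:
    name: str
    rule: str
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class CascadeReport:
    stages: list[CascadeStage]
    concordance_fraction: float | None

    @property
    def final_candidates(self) -> list[str]:
        return self.stages[-1].members if self.stages else []

    def counts(self) -> list[int]:
        return [s.count for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "rule": s.rule, "count": s.count, "members": s.members}
                for s in self.stages
            ],
            "concordance_fraction": self.concordance_fraction,
            "final_candidates": self.final_candidates,
        }


def candidate_cascade(
    diff_te_condition1: TEChange,
    diff_te_condition2: TEChange,
    m6a_set: GeneSet,
    rip_set: GeneSet,
    transl_log2fc_1: Mapping[str, float] | pd.Series,
    transl_log2fc_2: Mapping[str, float] | pd.Series,
    thresholds: Thresholds,
) -> CascadeReport:
    """Run the three-stage candidate cascade over two TE comparisons.

    ``diff_te_condition1``/``diff_te_condition2`` are TE comparisons for
    the two contrasts; ``transl_log2fc_*`` are the matching per-gene
    translatome log2 fold changes. Stage-1 differential TE means direction
    != unchanged in both (any direction); an empty stage 1 yields a valid
    report with empty downstream stages and a warning.
    """
    d1 = diff_te_condition1.records
    d2 = diff_te_condition2.records
    shared = d1.index.intersection(d2.index)
    diff1 = set(shared[(d1.loc[shared, "direction"] != "unchanged").to_numpy()])
    diff2 = set(shared[(d2.loc[shared, "direction"] != "unchanged").to_numpy()])
    stage1_members = sorted(diff1 & diff2 & m6a_set.members & rip_set.members)
    stage1 = CascadeStage(
        name="differential_te_m6a_rip",
        rule="TE direction != unchanged in both contrasts, in m6A set, in RIP consensus",
        members=stage1_members,
    )
    if not stage1_members:
        logger.warning("cascade stage 1 is empty; downstream stages will be empty")

    stage2_members = sorted(
        g
        for g in stage1_members
        if d1.loc[g, "direction"] == "down" and d2.loc[g, "direction"] == "down"
    )
    stage2 = CascadeStage(
        name="te_down_both",
        rule="TE direction down in both contrasts",
        members=stage2_members,
    )
    concordance = len(stage2_members) / len(stage1_members) if stage1_members else None

    fc1 = pd.Series(transl_log2fc_1, dtype=float)
    fc2 = pd.Series(transl_log2fc_2, dtype=float)
    cut = thresholds.concordant_log2fc
    stage3_members = sorted(
        g
        for g in stage2_members
        if g in fc1.index
        and g in fc2.index
        and fc1[g] < cut
        and fc2[g] < cut
    )
    stage3 = CascadeStage(
        name="translation_down_both",
        rule=f"translatome log2 FC < {cut} in both contrasts (strict)",
        members=stage3_members,
    )
    return CascadeReport(stages=[stage1, stage2, stage3], concordance_fraction=concordance)


@dataclass
class OverlapSummary:
    """Inclusion–exclusion partition of named gene sets.

    ``region_counts`` maps a membership signature (frozenset of set names
    the region's genes belong to) to a count; regions partition the union.
    ``shared_fraction`` = |intersection of all sets| / |reference set|.
    """

    set_names: list[str]
    set_sizes: dict[str, int]
    region_counts: dict[frozenset, int]
    reference: str
    shared_fraction: float

    def region_table(self) -> pd.DataFrame:
        rows = [
            {"sets": "&".join(sorted(sig)), "count": n}
            for sig, n in sorted(self.region_counts.items(), key=lambda kv: kv[0] and sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def overlap_analysis(
    sets: Sequence[GeneSet],
    reference: str,
    match_mode: str = "exact",
) -> OverlapSummary:
    """Venn-style overlap of >=2 named gene sets.

    ``match_mode='case_insensitive_symbol'`` uppercases ids before
    matching (the cross-species mouse/human symbol convention); ids within
    one set that collide after uppercasing are dropped with a logged count.
    """
    if len(sets) < 2:
        raise ValidationError("overlap_analysis needs >=2 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError("set names must be unique")
    if reference not in names:
        raise ValidationError(f"reference {reference!r} not among set names {names}")
    if match_mode not in ("exact", "case_insensitive_symbol"):
        raise ValidationError(f"unknown match_mode {match_mode!r}")

    normalized: dict[str, set[str]] = {}
    for s in sets:
        if match_mode == "exact":
            normalized[s.name] = set(s.members)
        else:
            seen: dict[str, int] = {}
            for g in s.members:
                seen[g.upper()] = seen.get(g.upper(), 0) + 1
            collisions = sum(1 for c in seen.values() if c > 1)
            if collisions:
                logger.warning(
                    "set %r: %d uppercased symbol collisions dropped", s.name, collisions
                )
            normalized[s.name] = {g for g, c in seen.items() if c == 1}

    union = set().union(*normalized.values())
    region_counts: dict[frozenset, int] = {}
    for g in union:
        sig = frozenset(n for n in names if g in normalized[n])
        region_counts[sig] = region_counts.get(sig, 0) + 1
    inter = set.intersection(*normalized.values())
    ref_size = len(normalized[reference])
    return OverlapSummary(
        set_names=names,
        set_sizes={n: len(normalized[n]) for n in names},
        region_counts=region_counts,
        reference=reference,
        shared_fraction=len(inter) / ref_size if ref_size else float("nan"),
    )


def concordance_scatter(
    log2fc_1: Mapping[str, float] | pd.Series,
    log2fc_2: Mapping[str, float] | pd.Series,
    genes: Sequence[str] | None = None,
) -> tuple[float, float, dict[str, int]]:
    """Pearson r of two log2 fold-change vectors plus sign-quadrant counts.

    Returns (r, two-sided p, quadrant counts with keys both_down, both_up,
    discordant_1up_2down, discordant_1down_2up). Genes with a zero fold
    change in either vector fall in no quadrant.
    """
    s1 = pd.Series(log2fc_1, dtype=float)
    s2 = pd.Series(log2fc_2, dtype=float)
    idx = s1.index.intersection(s2.index)
    if genes is not None:
        idx = idx.intersection(pd.Index(genes))
    if len(idx) < 3:
        raise ValidationError("need >=3 shared genes")
    x, y = s1[idx].to_numpy(), s2[idx].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in a fold-change vector")
    r, p = stats.pearsonr(x, y)
    quadrants = {
        "both_down": int(((x < 0) & (y < 0)).sum()),
        "both_up": int(((x > 0) & (y > 0)).sum()),
        "discordant_1up_2down": int(((x > 0) & (y < 0)).sum()),
        "discordant_1down_2up": int(((x < 0) & (y > 0)).sum()),
    }
    return float(r), float(p), quadrants
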