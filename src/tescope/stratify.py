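"""Stratified statistics over annotation groups, preranked GSEA, and
Fisher over-representation.

Group comparisons use a two-sided Welch t-test for two groups and one-way
ANOVA with Bonferroni-adjusted pairwise Welch post hocs for the 2x2 case.
Over-representation uses the two-tailed Fisher exact test with
Benjamini-Hochberg correction across sets.

Preranked GSEA is the weighted Kolmogorov-Smirnov-like running sum: genes
are ranked by score (descending, ties broken by gene id for determinism);
set members increment the sum by |score|^weight normalized over member
scores, non-members decrement by 1/(N - N_hit); the enrichment score (ES)
is the extremum of the running sum. The null is built from random
same-size gene sets (gene permutation — the standard choice for preranked
mode, where only the ranked list is available), and p is the
one-plus-corrected fraction of same-sign null scores at least as extreme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import GeneSet, ValidationError

__all__ = [
    "StratumStats",
    "GSEAResult",
    "compare_two_groups",
    "compare_four_groups",
    "preranked_gsea",
    "gsea_running_sum",
    "overrepresentation",
    "rbp_enrichment",
]


@dataclass
class StratumStats:
    """Result of a stratified comparison of per-gene values across groups."""

    grouping: list[str]
    n_per_group: dict[str, int]
    mean_per_group: dict[str, float]
    median_per_group: dict[str, float]
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # raw + Bonferroni-adjusted p per pair


@dataclass
class GSEAResult:
    """Preranked GSEA outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    p: float
    leading_edge: list[str]
    n_hits: int


def _group_values(
    values: pd.Series, labels: pd.Series
) -> dict[str, np.ndarray]:
    out = {}
    for label in labels.unique():
        out[str(label)] = values[labels == label].to_numpy(dtype=float)
    return out


def compare_two_groups(
    values: Mapping[str, float] | pd.Series,
    flag: Mapping[str, bool] | pd.Series,
    labels: tuple[str, str] = ("flag_false", "flag_true"),
) -> StratumStats:
    """Welch two-sided t-test of per-gene values split by a boolean flag.

    Typical use: log2 TE fold changes of m6A-flagged vs unflagged genes.
    """
    v = pd.Series(values, dtype=float)
    f = pd.Series(flag).reindex(v.index)
    if f.isna().any():
        raise ValidationError("flag missing for some genes in values")
    groups = {labels[0]: v[~f.astype(bool)], labels[1]: v[f.astype(bool)]}
    for name, g in groups.items():
        if len(g) < 2:
            raise ValidationError(f"group {name!r} has <2 members")
    t, p = stats.ttest_ind(
        groups[labels[1]], groups[labels[0]], equal_var=False
    )
    return StratumStats(
        grouping=list(labels),
        n_per_group={k: int(len(g)) for k, g in groups.items()},
        mean_per_group={k: float(g.mean()) for k, g in groups.items()},
        median_per_group={k: float(g.median()) for k, g in groups.items()},
        test="welch_t",
        statistic=float(t),
        p_value=float(p),
    )


def compare_four_groups(
    values: Mapping[str, float] | pd.Series,
    flag1: Mapping[str, bool] | pd.Series,
    flag2: Mapping[str, bool] | pd.Series,
    names: tuple[str, str] = ("flag1", "flag2"),
) -> StratumStats:
    """One-way ANOVA over the 2x2 cells of two boolean flags, with all six
    pairwise Welch comparisons Bonferroni-adjusted (x6).
    """
    v = pd.Series(values, dtype=float)
    f1 = pd.Series(flag1).reindex(v.index).astype(bool)
    f2 = pd.Series(flag2).reindex(v.index).astype(bool)
    n1, n2 = names
    cells: dict[str, np.ndarray] = {}
    for a in (False, True):
        for b in (False, True):
            label = f"{n1}{'+' if a else '-'}/{n2}{'+' if b else '-'}"
            cells[label] = v[(f1 == a) & (f2 == b)].to_numpy(dtype=float)
    empty = [k for k, g in cells.items() if len(g) < 2]
    if empty:
        raise ValidationError(f"cells with <2 members: {empty}")
    f_stat, p = stats.f_oneway(*cells.values())
    pairs = list(itertools.combinations(cells.keys(), 2))
    rows = []
    for a, b in pairs:
        t, praw = stats.ttest_ind(cells[a], cells[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(praw),
                "p_bonferroni": min(1.0, float(praw) * len(pairs)),
            }
        )
    return StratumStats(
        grouping=list(cells.keys()),
        n_per_group={k: int(len(g)) for k, g in cells.items()},
        mean_per_group={k: float(g.mean()) for k, g in cells.items()},
        median_per_group={k: float(np.median(g)) for k, g in cells.items()},
        test="anova_bonferroni",
        statistic=float(f_stat),
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
    )


def _ranked(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(scores, dtype=float)
    # descending score; ties broken by gene id ascending for determinism
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s[order]


def gsea_running_sum(
    ranked_scores: pd.Series, member_mask: np.ndarray, weight: float
) -> np.ndarray:
    """Running enrichment sum over an already-ranked score vector."""
    n = len(ranked_scores)
    n_hit = int(member_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must be a non-empty proper subset of the ranking")
    w = np.abs(ranked_scores.to_numpy()) ** weight
    hit_weights = np.where(member_mask, w, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # all member scores are exactly 0 at weight>0: fall back to equal weights
        hit_weights = member_mask.astype(float)
        total = hit_weights.sum()
    steps = hit_weights / total - (~member_mask) / (n - n_hit)
    return np.cumsum(steps)


def preranked_gsea(
    ranking: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Preranked gene-set enrichment with a gene-permutation null.

    p = (1 + #{null ES at least as extreme, same sign}) / (1 + #{null same
    sign}); NES = ES / mean(|null ES| of the same sign). The leading edge
    is the member genes at or before the ES extremum (after it, for
    negative ES).
    """
    scores = _ranked(ranking)
    if len(scores) < 2:
        raise ValidationError("ranking needs >=2 genes")
    genes = np.array(scores.index)
    member_mask = np.isin(genes, list(gene_set.members))
    n_hit = int(member_mask.sum())
    running = gsea_running_sum(scores, member_mask, weight)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])

    rng = np.random.default_rng(seed)
    n = len(genes)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n_hit, replace=False)] = True
        r = gsea_running_sum(scores, perm_mask, weight)
        null_es[i] = r[np.argmax(np.abs(r))]

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    extreme = np.abs(null_es[same_sign]) >= abs(es)
    p = (1 + int(extreme.sum())) / (1 + int(same_sign.sum()))
    mean_null = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / mean_null if mean_null and np.isfinite(mean_null) and mean_null > 0 else np.nan

    if es >= 0:
        leading = [g for g, m in zip(genes[: peak + 1], member_mask[: peak + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[peak:], member_mask[peak:]) if m]
    return GSEAResult(
        set_name=gene_set.name,
        es=es,
        nes=float(nes),
        p=float(p),
        leading_edge=leading,
        n_hits=n_hit,
    )


def overrepresentation(
    foreground: Iterable[str],
    universe: Iterable[str],
    sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """Two-tailed Fisher exact over-representation of a foreground list.

    Per set: a 2x2 table of (in/out foreground) x (in/out set), restricted
    to the universe; BH-adjusted across sets. The odds ratio gets a
    Haldane correction (+0.5 per cell) when any cell is zero.

    Returns a DataFrame indexed by set name with columns
    ``overlap_count, set_in_universe, foreground_count, universe_count,
    odds_ratio, p, fdr``.
    """
    fg = set(foreground)
    uni = set(universe)
    if not fg <= uni:
        raise ValidationError("foreground must be a subset of the universe")
    rows = []
    for gs in sets:
        in_set = gs.members & uni
        a = len(fg & in_set)                 # fg, in set
        b = len(fg) - a                       # fg, out of set
        c = len(in_set) - a                   # bg, in set
        d = len(uni) - len(fg) - c            # bg, out of set
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            {
                "set_name": gs.name,
                "overlap_count": a,
                "set_in_universe": len(in_set),
                "foreground_count": len(fg),
                "universe_count": len(uni),
                "odds_ratio": float(orr),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def rbp_enrichment(
    occurrence: pd.DataFrame,
    foreground: Iterable[str],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """RBP-motif enrichment in a gene list's 3'UTRs.

    ``occurrence`` is a genes x RBPs boolean table (True iff the RBP's
    motif occurs at least once in that gene's 3'UTR); each RBP becomes a
    gene set and the result reduces to :func:`overrepresentation`, sorted
    by FDR then set name.
    """
    uni = list(universe) if universe is not None else list(occurrence.index)
    sets = [
        GeneSet.from_iterable(str(rbp), occurrence.index[occurrence[rbp].astype(bool)])
        for rbp in occurrence.columns
    ]
    out = overrepresentation(foreground, uni, sets)
    return out.sort_values(["fdr", "p", "set_name"], kind="mergesort")
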