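"""Target-set definition and expression-side summaries.

Genes are ranked by the combined target score; a gene whose score reaches
the threshold (default 1.75) enters the target set.  Ranked genes are cut
into consecutive groups (default 250) to track how often a sequence feature
(typically the 7-mer seed match) occurs down the ranking relative to all
genes profiled, and per-class repression distributions are compared with
empirical CDFs and Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

ORDERINGS = {"by_enrichment": "enrichment", "by_repression": "repression", "by_score": "score"}


def flag_targets(measures: pd.DataFrame, threshold: float = 1.75) -> pd.DataFrame:
    """Return a copy of the measures with an ``is_target`` column.

    ``is_target`` is score >= threshold (boundary inclusive).
    """
    out = measures.copy()
    out["is_target"] = out["score"] >= threshold
    return out


def select_target_set(measures: pd.DataFrame, threshold: float = 1.75) -> pd.DataFrame:
    """The target set: genes scoring at or above the threshold.

    Sorted by descending score; ties broken lexicographically by gene ID
    for determinism.
    """
    flagged = flag_targets(measures, threshold)
    targets = flagged[flagged["is_target"]]
    return targets.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def rank_genes(measures: pd.DataFrame, ordering: str = "by_score") -> list[str]:
    """Gene IDs ranked from highest to lowest on the chosen measure."""
    if ordering not in ORDERINGS:
        raise InputError(f"unknown ordering {ordering!r}; expected one of {sorted(ORDERINGS)}")
    col = ORDERINGS[ordering]
    ranked = measures.sort_values(
        [col, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked["gene_id"].tolist()


@dataclass(frozen=True)
class RankedGroups:
    """Consecutive groups of ranked genes (last group may be short)."""

    ordering: str
    group_size: int
    groups: tuple[tuple[str, ...], ...]

    @property
    def all_genes(self) -> list[str]:
        return [g for grp in self.groups for g in grp]


def make_ranked_groups(
    measures: pd.DataFrame, ordering: str = "by_score", group_size: int = 250
) -> RankedGroups:
    if group_size < 1:
        raise InputError("group_size must be >= 1")
    ranked = rank_genes(measures, ordering)
    groups = tuple(
        tuple(ranked[i : i + group_size]) for i in range(0, len(ranked), group_size)
    )
    return RankedGroups(ordering=ordering, group_size=group_size, groups=groups)


def group_feature_frequency(
    ranked: RankedGroups, feature_genes: Iterable[str], background: Iterable[str]
) -> np.ndarray:
    """Per-group feature frequency relative to the background frequency.

    For each group: (fraction of the group carrying the feature) /
    (fraction of the background carrying it).  The group-size-weighted mean
    over all groups is 1 when the groups partition the background.
    """
    feature = set(feature_genes)
    bg = set(background)
    if not feature <= bg:
        raise InputError("feature genes must be a subset of the background")
    if not bg:
        raise InputError("background gene set is empty")
    bg_freq = len(feature & bg) / len(bg)
    if bg_freq == 0:
        raise InputError("feature frequency in the background is zero; ratio undefined")
    return np.array(
        [sum(g in feature for g in grp) / len(grp) / bg_freq for grp in ranked.groups]
    )


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, x.size + 1) / x.size


def cdf_repression_by_class(
    measures: pd.DataFrame,
    classes: Mapping[str, Iterable[str]],
    reference: str = "all",
) -> dict:
    """Empirical CDFs of log2 repression per gene class, plus Welch t-tests.

    Each class is compared with the ``reference`` class ("all" by default,
    added automatically as every gene in ``measures`` if absent) by a
    two-sided Welch t-test on log2 repression.  A class with fewer than two
    members gets its CDF but no test.
    """
    if not classes:
        raise InputError("at least one gene class is required")
    by_gene = measures.set_index("gene_id")["repression"]
    classes = dict(classes)
    if reference not in classes:
        classes[reference] = list(by_gene.index)
    log2_values = {
        name: np.log2(by_gene.loc[[g for g in genes if g in by_gene.index]].to_numpy(float))
        for name, genes in classes.items()
    }
    ref = log2_values[reference]
    cdfs = {name: _ecdf(vals) for name, vals in log2_values.items() if vals.size}
    tests = {}
    for name, vals in log2_values.items():
        if name == reference:
            continue
        if vals.size < 2 or ref.size < 2:
            tests[name] = {"t": np.nan, "p_value": np.nan, "computed": False}
            continue
        t, p = stats.ttest_ind(vals, ref, equal_var=False)
        tests[name] = {"t": float(t), "p_value": float(p), "computed": True}
    return {"log2_repression": log2_values, "cdf": cdfs, "tests": tests, "reference": reference}


def enrichment_repression_correlation(
    measures: pd.DataFrame, log_scale: bool = True
) -> float:
    """Pearson correlation between enrichment and repression across genes.

    Computed on log2 ratios by default (ratios are multiplicative; the log
    symmetrises up- and down-changes).
    """
    if len(measures) < 3:
        raise InputError("at least 3 genes are required for a correlation")
    e = measures["enrichment"].to_numpy(float)
    r = measures["repression"].to_numpy(float)
    if log_scale:
        e, r = np.log2(e), np.log2(r)
    if np.allclose(e, e[0]) or np.allclose(r, r[0]):
        raise InputError("zero variance in enrichment or repression; correlation undefined")
    return float(stats.pearsonr(e, r).statistic)
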