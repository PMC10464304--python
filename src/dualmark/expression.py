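"""Microarray differential-regulation calls and enhancer-mark association.

Probe-level log2 fold changes (rescue condition vs mock) are collapsed to
gene level by the per-gene median, genes are classified as up / down /
non-responding against a linear fold-change threshold (default 1.5, i.e.
|log2 FC| >= log2 1.5, boundary inclusive), and the reader-dependent set
is the intersection of wild-type non-responders with the reader-dead
(TTD*) up-set. The association stage compares enhancer mark levels
between gene groups with a classical one-way ANOVA plus Bonferroni-
corrected pairwise t-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gene_medians",
    "call_drgs",
    "DRGSets",
    "ttd_dependent_set",
    "mark_association",
    "EnhancerAssociation",
    "expression_ratio_bins",
]


def gene_medians(probe_table: pd.DataFrame, condition_cols=None) -> pd.DataFrame:
    """Per-gene median of probe-level log2 FC for each condition column.

    Duplicate gene symbols are merged by symbol before the median; genes
    with zero probes simply do not appear.
    """
    if "gene" not in probe_table.columns:
        raise ValueError("probe table must carry a 'gene' column")
    if condition_cols is None:
        condition_cols = [
            c for c in probe_table.columns if c not in ("probe_id", "gene")
        ]
    return (
        probe_table.groupby("gene", sort=True)[list(condition_cols)]
        .median()
        .reset_index()
    )


@dataclass
class DRGSets:
    """Partition of the gene universe into up / down / non-responding."""

    up: set[str]
    down: set[str]
    non_responding: set[str]
    threshold_fold: float

    @property
    def universe(self) -> set[str]:
        return self.up | self.down | self.non_responding


def call_drgs(
    gene_table: pd.DataFrame, condition: str, fc_threshold: float = 1.5
) -> DRGSets:
    """Classify genes by median log2 FC against a linear fold threshold.

    A gene is up when FC >= threshold, i.e. log2 FC >= log2(threshold),
    down when log2 FC <= -log2(threshold); the boundary is inclusive.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1 (linear fold scale)")
    if condition not in gene_table.columns:
        raise KeyError(f"no condition column {condition!r}")
    cut = math.log2(fc_threshold)
    lfc = gene_table[condition].to_numpy()
    genes = gene_table["gene"].to_numpy()
    up = set(genes[lfc >= cut])
    down = set(genes[lfc <= -cut])
    non = set(genes) - up - down
    return DRGSets(up=up, down=down, non_responding=non, threshold_fold=fc_threshold)


def ttd_dependent_set(drg_wt: DRGSets, drg_ttdstar: DRGSets) -> set[str]:
    """Genes silent under WT rescue but upregulated under TTD* rescue."""
    if drg_wt.universe != drg_ttdstar.universe:
        raise ValueError("DRG sets come from different gene universes")
    return drg_wt.non_responding & drg_ttdstar.up


@dataclass
class EnhancerAssociation:
    summaries: pd.DataFrame  # per-group n, median, quartiles, p5/p95
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_bonferroni
    degenerate: bool = False


def mark_association(
    groups: dict[str, set[str]],
    enhancer_table: pd.DataFrame,
    mark: str = "k4me1",
) -> EnhancerAssociation:
    """Compare an enhancer mark between gene groups (one-way ANOVA).

    ``groups`` maps a label (e.g. "TTD*-up", "non-responding") to a gene
    set; every enhancer mapped to a grouped gene contributes its mark
    value to that group. Pairwise p-values are two-sided pooled-variance
    t-tests multiplied by the number of comparisons (capped at 1).
    """
    samples: dict[str, np.ndarray] = {}
    for label, gene_set in groups.items():
        vals = enhancer_table.loc[enhancer_table["gene"].isin(gene_set), mark]
        samples[label] = vals.to_numpy(dtype=float)
        if len(samples[label]) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 enhancers with signal")

    rows = []
    for label, v in samples.items():
        q = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95])
        rows.append(
            {
                "group": label,
                "n": len(v),
                "p5": q[0],
                "p25": q[1],
                "median": q[2],
                "p75": q[3],
                "p95": q[4],
                "mean": v.mean(),
            }
        )
    summaries = pd.DataFrame(rows)

    arrays = list(samples.values())
    if all(np.ptp(a) == 0 for a in arrays):
        flat = np.concatenate(arrays)
        if np.ptp(flat) == 0:  # identical constant everywhere: no test possible
            return EnhancerAssociation(
                summaries=summaries,
                anova_F=0.0,
                anova_p=1.0,
                pairwise=pd.DataFrame(columns=["group_a", "group_b", "t", "p_bonferroni"]),
                degenerate=True,
            )
    F, p = stats.f_oneway(*arrays)
    labels = list(samples)
    pairs = list(itertools.combinations(labels, 2))
    prows = []
    for a, b in pairs:
        t, pt = stats.ttest_ind(samples[a], samples[b], equal_var=True)
        prows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_bonferroni": min(1.0, float(pt) * len(pairs)),
            }
        )
    return EnhancerAssociation(
        summaries=summaries,
        anova_F=float(F),
        anova_p=float(p),
        pairwise=pd.DataFrame(prows),
    )


def expression_ratio_bins(
    gene_table: pd.DataFrame,
    level_a: str,
    level_b: str,
    signal: str,
    min_level: float = 1000.0,
    min_fold: float = 2.0,
    k: int = 5,
) -> pd.DataFrame:
    """Filter genes by expression level/fold and bin them by ratio.

    Keeps genes with ratio a/b >= min_fold or <= 1/min_fold AND
    max(level_a, level_b) >= min_level, ranks them by ascending ratio
    (ties broken by gene name) and splits them into k near-equal bins.
    Returns a per-gene table with ``bin`` (1 = lowest ratio) plus the
    associated signal column, ready for per-bin summaries.
    """
    df = gene_table.copy()
    if (df[[level_a, level_b]] < 0).to_numpy().any():
        raise ValueError("expression levels must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = df[level_a] / df[level_b]
    keep = ((ratio >= min_fold) | (ratio <= 1.0 / min_fold)) & (
        df[[level_a, level_b]].max(axis=1) >= min_level
    )
    df = df[keep].copy()
    df["ratio"] = ratio[keep]
    if len(df) < k:
        raise ValueError(f"only {len(df)} genes pass the filter; need >= {k}")
    df = df.sort_values(["ratio", "gene"], kind="stable").reset_index(drop=True)
    n = len(df)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    df["bin"] = np.repeat(np.arange(1, k + 1), sizes)
    return df[["gene", level_a, level_b, "ratio", "bin", signal]]
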