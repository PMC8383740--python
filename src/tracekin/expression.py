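"""Count-matrix survey rules: paralog grouping, normalization, expression
calls, DEG classification and per-cell CPM summaries.

Gene-family paralogs whose reads cannot be distinguished (e.g. FCGR2A/B/C)
are summed into one row with a summed length before any normalization, so
per-kilobase values stay consistent. The DEG rule is: differentially
expressed iff adjusted p < 0.05 and linear fold change >= 1.5 in either
direction; non-DEGs with adjusted-or-nominal p < 0.10 are trend calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DEFAULT_PARALOG_GROUPS",
    "group_paralogs",
    "size_factors",
    "normalized_per_kb",
    "tpm",
    "expression_calls",
    "bh_adjust",
    "nb_wald_test",
    "deg_classify",
    "sc_cpm",
]

logger = logging.getLogger(__name__)

DEFAULT_PARALOG_GROUPS: dict[str, list[str]] = {
    "FCGR2": ["FCGR2A", "FCGR2B", "FCGR2C"],
    "FCGR3": ["FCGR3A", "FCGR3B"],
}

TPM_EXPRESSED = 1.0
TPM_VERY_LOW = 0.5
TPM_RANKING = 0.25
TPM_BASAL = 1.2

DEG_PADJ = 0.05
DEG_FC = 1.5
TREND_P = 0.10


@dataclass
class CountMatrix:
    """Gene x sample integer counts with lengths and group labels.

    gene_lengths are in kilobases.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_groups: dict[str, str] = field(default_factory=dict)
    paralog_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            raise ValueError("gene names must be unique")
        self.gene_lengths = pd.Series(self.gene_lengths).reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths[self.gene_lengths.isna()].index.tolist()
            raise ValueError(f"missing gene lengths for {missing[:5]}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        lengths_path: str | Path,
        sample_groups: Mapping[str, str] | None = None,
        sep: str = "\t",
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep=sep, index_col=0)
        lengths = pd.read_csv(lengths_path, sep=sep, index_col=0).iloc[:, 0]
        return cls(counts, lengths, dict(sample_groups or {}))


def group_paralogs(
    matrix: CountMatrix, groups: Mapping[str, Sequence[str]] | None = None
) -> CountMatrix:
    """Sum indistinguishable paralog rows into one row per group.

    Grouped counts are member sums and the grouped length is the member
    length sum; member rows are removed. Missing members are logged, not
    fatal; overlapping groups are an error.
    """
    groups = dict(groups if groups is not None else (matrix.paralog_groups or DEFAULT_PARALOG_GROUPS))
    seen: set[str] = set()
    for name, members in groups.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"paralog groups overlap on {sorted(overlap)}")
        seen |= set(members)

    counts = matrix.counts.copy()
    lengths = matrix.gene_lengths.copy()
    for name, members in groups.items():
        present = [m for m in members if m in counts.index]
        absent = sorted(set(members) - set(present))
        if absent:
            logger.info("paralog group %s: members not found: %s", name, absent)
        if not present:
            continue
        grouped_counts = counts.loc[present].sum(axis=0)
        grouped_len = lengths.loc[present].sum()
        counts = counts.drop(index=present)
        lengths = lengths.drop(index=present)
        counts.loc[name] = grouped_counts
        lengths.loc[name] = grouped_len
    return CountMatrix(counts, lengths, dict(matrix.sample_groups), {})


def size_factors(matrix: CountMatrix | pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library-size factors.

    Each sample's factor is the median, over genes with a positive geometric
    mean across samples, of count/geometric-mean. Requires at least one gene
    expressed in every sample unless ``allow_pseudo_reference`` relaxes the
    reference to genes nonzero in any sample.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else pd.DataFrame(matrix)
    arr = counts.to_numpy(dtype=float)
    all_pos = np.all(arr > 0, axis=1)
    if all_pos.any():
        sub = arr[all_pos]
        geo = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    else:
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with allow_pseudo_reference=True"
            )
        # poscounts-style: geometric mean over positive entries only,
        # per-sample medians over the genes observed in that sample
        any_pos = np.any(arr > 0, axis=1)
        sub = arr[any_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        with np.errstate(invalid="ignore"):
            ratios = np.where(sub > 0, sub / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
        if np.any(~np.isfinite(factors)):
            raise ValueError("size factors undefined for samples with no counts")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_per_kb(
    matrix: CountMatrix, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Library-normalized reads per kilobase: (count / factor) / length_kb."""
    factors = factors if factors is not None else size_factors(matrix)
    normed = matrix.counts.div(factors, axis=1)
    return normed.div(matrix.gene_lengths, axis=0)


def tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized to 1e6 per sample.

    All-zero samples yield all-zero columns with a warning.
    """
    rate = matrix.counts.div(matrix.gene_lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero counts in samples: %s", list(totals.index[zero]))
        totals = totals.mask(zero, 1.0)
    return rate.div(totals, axis=1) * 1e6


def expression_calls(
    tpm_matrix: pd.DataFrame, subsets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Classify per-subset mean TPM against the 1 / 0.5 / 0.25 thresholds.

    All thresholds are inclusive (>=). ``basal_flag`` marks genes whose mean
    TPM reaches 1.2 in at least one subset.
    """
    rows = []
    for subset, samples in subsets.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"subset {subset!r} is empty")
        missing = [s for s in samples if s not in tpm_matrix.columns]
        if missing:
            raise KeyError(f"subset {subset!r}: samples not in matrix: {missing}")
        means = tpm_matrix[samples].mean(axis=1)
        call = pd.cut(
            means,
            bins=[-np.inf, TPM_RANKING, TPM_VERY_LOW, TPM_EXPRESSED, np.inf],
            labels=["absent", "below_ranking", "very_low", "expressed"],
            right=False,
        )
        rows.append(
            pd.DataFrame(
                {"gene": means.index, "subset": subset, "mean_tpm": means.to_numpy(),
                 "call": call.to_numpy()}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    basal = out.groupby("gene")["mean_tpm"].max() >= TPM_BASAL
    out["basal_flag"] = basal.reindex(out["gene"]).to_numpy()
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw, idempotent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def nb_wald_test(
    matrix: CountMatrix, group_a: str, group_b: str, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Convenience per-gene NB Wald test of group B vs group A.

    Method-of-moments dispersion with no shrinkage; this is deliberately a
    simple built-in, not a DESeq2 clone — externally computed statistics are
    the higher-fidelity input to :func:`deg_classify`. Returns log2 fold
    change (B over A), raw p and BH-adjusted p per gene.
    """
    sa, sb = matrix.group_samples(group_a), matrix.group_samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            "built-in test needs >= 2 samples per group; supply external "
            "per-gene statistics to deg_classify instead"
        )
    factors = factors if factors is not None else size_factors(matrix)
    normed = matrix.counts.div(factors, axis=1)
    a = normed[sa].to_numpy(dtype=float)
    b = normed[sb].to_numpy(dtype=float)
    pseudo = 0.5
    mu_a = a.mean(axis=1) + pseudo
    mu_b = b.mean(axis=1) + pseudo

    # method-of-moments dispersion pooled within groups: var = mu + alpha mu^2;
    # gene-wise estimates are noisy at small n, so floor at the global median
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    n_a, n_b = len(sa), len(sb)
    excess = ((n_a - 1) * (var_a - mu_a) + (n_b - 1) * (var_b - mu_b)) / (n_a + n_b - 2)
    denom = 0.5 * (mu_a**2 + mu_b**2)
    alpha_gene = np.clip(excess / denom, 0.0, 10.0)
    alpha = np.maximum(alpha_gene, np.median(alpha_gene))

    log2fc = np.log2(mu_b / mu_a)
    # delta-method variance of log(mean) per group: (1/n)(1/mu + alpha);
    # t reference with n-2 df guards the small-sample tails
    se2 = (1.0 / mu_a + alpha) / n_a + (1.0 / mu_b + alpha) / n_b
    z = np.log(mu_b / mu_a) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(z), df=n_a + n_b - 2)
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_raw": p,
            "p_adjusted": bh_adjust(p),
            "dispersion": alpha,
        },
        index=matrix.genes,
    )


def deg_classify(
    stats_table: pd.DataFrame | None = None,
    matrix: CountMatrix | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Apply the DEG/trend classification rule to per-gene statistics.

    Accepts a table with ``log2_fold_change``, ``p_raw`` and ``p_adjusted``
    columns (external statistics), or a matrix plus two group labels for the
    built-in test. Classes: ``DEG_up``/``DEG_down`` when adjusted p < 0.05
    and |FC| >= 1.5 in either direction; ``up_trend``/``down_trend`` when not
    a DEG but adjusted or nominal p < 0.10; otherwise ``ns``.
    """
    if stats_table is None:
        if matrix is None or group_a is None or group_b is None:
            raise ValueError("provide stats_table, or matrix with two group labels")
        stats_table = nb_wald_test(matrix, group_a, group_b)
    t = stats_table.copy()
    for col in ("log2_fold_change", "p_raw", "p_adjusted"):
        if col not in t.columns:
            raise KeyError(f"stats table missing column {col!r}")
    lfc = t["log2_fold_change"].to_numpy(dtype=float)
    praw = t["p_raw"].to_numpy(dtype=float)
    padj = t["p_adjusted"].to_numpy(dtype=float)
    is_deg = (padj < DEG_PADJ) & (np.abs(lfc) >= np.log2(DEG_FC))
    is_trend = ~is_deg & ((padj < TREND_P) | (praw < TREND_P))
    cls = np.where(
        is_deg,
        np.where(lfc > 0, "DEG_up", "DEG_down"),
        np.where(is_trend, np.where(lfc > 0, "up_trend", "down_trend"), "ns"),
    )
    t["class"] = cls
    summary = pd.Series(cls).value_counts().to_dict()
    logger.info("DEG classification counts: %s", summary)
    return t


def sc_cpm(
    cell_counts: pd.DataFrame, gene_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-cell counts-per-million of summed gene groups.

    ``cell_counts`` is gene x cell. Cells with zero total counts are dropped
    (logged). Returns cells x groups, each value
    1e6 * (group count sum) / (cell total counts).
    """
    totals = cell_counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping %d zero-total cells", int(zero.sum()))
    kept = cell_counts.loc[:, ~zero]
    out = {}
    for name, members in gene_groups.items():
        present = [m for m in members if m in kept.index]
        group_sum = kept.loc[present].sum(axis=0) if present else pd.Series(0.0, index=kept.columns)
        out[name] = 1e6 * group_sum / totals[~zero]
    return pd.DataFrame(out)
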