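"""Ranked-list gene-set enrichment and DEG-overlap testing.

The enrichment score is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-like running sum over a descending ranked list: hits add
``|score|^p / sum_hits |score|^p`` and misses subtract ``1/(N - n_set)``.
Significance uses gene-set permutations (default) with the positive/negative
null-pool NES ratio for the FDR q-value; a set is "enriched" at q < 0.25.
DEG overlap against a stated universe uses the upper-tail hypergeometric
with BH adjustment and a q < 0.005 significance flag by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "RankedList",
    "read_gmt",
    "write_gmt",
    "signal2noise",
    "rank_by_signal2noise",
    "enrichment_score",
    "permutation_fdr",
    "overlap_test",
]

logger = logging.getLogger(__name__)

ENRICHED_Q = 0.25
MIN_SET_SIZE = 15
MAX_SET_SIZE = 500


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending ranking score."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __init__(self, genes: Sequence[str], scores: Sequence[float]):
        genes = tuple(genes)
        scores = np.asarray(scores, dtype=float)
        if len(genes) != scores.size:
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("genes must be unique")
        order = np.argsort(-scores, kind="stable")
        object.__setattr__(self, "genes", tuple(genes[i] for i in order))
        object.__setattr__(self, "scores", scores[order])

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_rnk(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].to_numpy(float))

    def to_rnk(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", header=False, index=False
        )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def signal2noise(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Per-gene (mu_A - mu_B) / (sigma_A + sigma_B) with floored sigmas.

    Each group sigma is floored at max(0.2*|group mean|, 0.2), the reference
    GSEA convention, keeping every score finite. Requires >= 2 samples per
    group; with fewer, rank by log2 fold change instead.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            "signal-to-noise needs >= 2 samples per group; "
            "use a log2 fold-change ranking for single-replicate designs"
        )
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_b), 0.2))
    return pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=matrix.index, name="s2n")


def rank_by_signal2noise(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> RankedList:
    s = signal2noise(matrix, group_a, group_b)
    return RankedList(list(s.index), s.to_numpy())


def _es_profile(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    n = scores.size
    n_hits = int(hits.sum())
    weights = np.abs(scores) ** weight
    hit_weights = np.where(hits, weights, 0.0)
    hit_total = hit_weights.sum()
    if hit_total == 0:  # all hit scores zero: fall back to unweighted steps
        hit_weights = hits.astype(float)
        hit_total = float(n_hits)
    miss_step = 1.0 / (n - n_hits) if n > n_hits else 0.0
    steps = hit_weights / hit_total - np.where(hits, 0.0, miss_step)
    return np.cumsum(steps)


def _es_from_profile(profile: np.ndarray) -> float:
    i_max, i_min = int(np.argmax(profile)), int(np.argmin(profile))
    return float(profile[i_max] if profile[i_max] >= -profile[i_min] else profile[i_min])


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile.

    Returns (ES, profile) where ES is the extremum of the profile with the
    largest absolute value (positive on ties) and profile has one entry per
    ranked gene.
    """
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    if not hits.any():
        raise ValueError("gene set has no overlap with the ranked list")
    profile = _es_profile(ranked.scores, hits, weight)
    return _es_from_profile(profile), profile


def leading_edge(ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0) -> list[str]:
    """Hit genes up to (down to) the running-sum extremum."""
    es, profile = enrichment_score(ranked, gene_set, weight)
    members = set(gene_set)
    if es >= 0:
        cut = int(np.argmax(profile))
        return [g for g in ranked.genes[: cut + 1] if g in members]
    cut = int(np.argmin(profile))
    return [g for g in ranked.genes[cut + 1 :] if g in members]


def _normalize(es: float | np.ndarray, null_es: np.ndarray):
    """NES: ES divided by the mean |null ES| of the same sign."""
    pos = null_es[null_es >= 0]
    neg = null_es[null_es < 0]
    pos_mean = pos.mean() if pos.size else np.nan
    neg_mean = np.abs(neg).mean() if neg.size else np.nan
    es_arr = np.atleast_1d(np.asarray(es, dtype=float))
    out = np.where(es_arr >= 0, es_arr / pos_mean, es_arr / neg_mean)
    return out if np.ndim(es) else float(out[0])


def permutation_fdr(
    ranked: RankedList | Callable[[np.random.Generator], RankedList],
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    mode: str = "gene_set",
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Permutation-based GSEA over a gene-set collection.

    mode="gene_set" (default) builds each set's null from random same-size
    gene sets drawn from the ranked list. mode="phenotype" instead expects
    ``ranked`` to be a callable mapping a numpy Generator to a re-ranked list
    (e.g. re-computing signal-to-noise under shuffled labels); the observed
    ranking is ``ranked(None)``.

    Returns one row per retained set: ES, NES, nominal p, FDR q (null-pool
    NES ratio, same-sign pools) and the enriched flag at q < 0.25.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    if mode == "phenotype":
        if not callable(ranked):
            raise ValueError("phenotype mode requires a ranking builder callable")
        observed = ranked(None)
    elif mode == "gene_set":
        if callable(ranked):
            observed = ranked(None)
        else:
            observed = ranked
    else:
        raise ValueError(f"unknown mode {mode!r}")

    universe = set(observed.genes)
    n = len(observed)
    kept: dict[str, list[str]] = {}
    for name, members in gene_sets.items():
        inside = [g for g in members if g in universe]
        if not inside:
            logger.info("skipping %s: no overlap with ranked list", name)
            continue
        if not (min_size <= len(inside) <= max_size):
            logger.info("skipping %s: size %d outside [%d, %d]", name, len(inside), min_size, max_size)
            continue
        kept[name] = inside
    if not kept:
        return pd.DataFrame(
            columns=["ES", "NES", "p_nominal", "fdr_q", "enriched", "size", "leading_edge"]
        )

    results = {}
    all_null_nes: list[np.ndarray] = []
    perm_rankings = None
    if mode == "phenotype":
        perm_rankings = [ranked(rng) for _ in range(n_perm)]

    scores = observed.scores
    for name, members in kept.items():
        es, _ = enrichment_score(observed, members, weight)
        size = len(members)
        null_es = np.empty(n_perm)
        if mode == "gene_set":
            for j in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                null_es[j] = _es_from_profile(_es_profile(scores, mask, weight))
        else:
            for j, perm_ranked in enumerate(perm_rankings):
                null_es[j], _ = enrichment_score(perm_ranked, members, weight)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            logger.warning("%s: all null ES are of the opposite sign; p and q set to 1", name)
            p_nom, nes, null_nes = 1.0, np.nan, np.array([])
        else:
            p_nom = float(np.mean(np.abs(null_es[same_sign]) >= abs(es)))
            nes = _normalize(es, null_es)
            null_nes = np.asarray(_normalize(null_es, null_es))
        results[name] = {"ES": es, "NES": nes, "p_nominal": p_nom, "size": size}
        all_null_nes.append(null_nes)

    pooled_null = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    obs_nes = np.array([r["NES"] for r in results.values()])
    rows = []
    for (name, r), members in zip(results.items(), kept.values()):
        nes = r["NES"]
        if not np.isfinite(nes):
            q = 1.0
        elif nes >= 0:
            num_pool = pooled_null[pooled_null >= 0]
            num = np.mean(num_pool >= nes) if num_pool.size else 1.0
            obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
            den = np.mean(obs_pool >= nes) if obs_pool.size else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        else:
            num_pool = pooled_null[pooled_null < 0]
            num = np.mean(num_pool <= nes) if num_pool.size else 1.0
            obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            den = np.mean(obs_pool <= nes) if obs_pool.size else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        rows.append(
            {
                "gene_set": name,
                "ES": r["ES"],
                "NES": nes,
                "p_nominal": r["p_nominal"],
                "fdr_q": q,
                "enriched": q < ENRICHED_Q,
                "size": r["size"],
                "leading_edge": ",".join(leading_edge(observed, members, weight)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


def overlap_test(
    deg_list: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    significant_q: float = 0.005,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of a DEG list with each gene set.

    The universe is an explicit required input; set members outside it are
    intersected away with a warning. BH-adjusted q-values are flagged
    significant below ``significant_q``.
    """
    uni = set(universe)
    degs = set(deg_list)
    outside = degs - uni
    if outside:
        raise ValueError(f"DEG list contains genes outside the universe: {sorted(outside)[:5]}")
    m = len(uni)
    n_deg = len(degs)
    rows = []
    for name, members in gene_sets.items():
        inside = set(members) & uni
        if len(inside) < len(set(members)):
            logger.warning(
                "%s: %d members outside the universe were dropped",
                name, len(set(members)) - len(inside),
            )
        k = len(inside & degs)
        # P(overlap >= k) with M=universe, K=set size, n=DEG draws
        p = float(stats.hypergeom.sf(k - 1, m, len(inside), n_deg)) if inside else 1.0
        rows.append({"gene_set": name, "set_size": len(inside), "overlap": k, "p_raw": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["fdr_q"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["fdr_q"] < significant_q
    return out
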