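"""Precursor-normalized proliferation statistics and condition comparisons.

The central quantity is the percent-undivided statistic

    Phi_1 = 100 * X_1 / (X_1 + sum_{i=1..D} X_{i+1} / 2^i)

where X_1..X_{D+1} are measured per-generation event frequencies and D is
the number of observed divisions. Dividing X_{g} by 2^(g-1) converts cell
frequencies back to the precursor (cohort) scale, so Phi_1 is exactly the
fraction of input cells that never divided. Phi_k applies the same formula
to the sub-vector X_k..X_{D+1}; theta_i = 100 - Phi_i is percent division.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import GenerationFrequencies

__all__ = [
    "ProliferationSummary",
    "ComparisonResult",
    "percent_undivided",
    "phi_series",
    "theta_series",
    "proliferation_indices",
    "holm_sidak",
    "compare_conditions",
    "summarize",
]

logger = logging.getLogger(__name__)


def _as_freqs(X) -> np.ndarray:
    if isinstance(X, GenerationFrequencies):
        X = X.X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("X must be a non-empty 1-D vector")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("frequencies must be finite and non-negative")
    if arr.sum() <= 0:
        raise ValueError("all-zero frequency vector")
    return arr


def _precursors(X: np.ndarray, dilution_factor: float = 2.0) -> np.ndarray:
    """Cohort counts n_g = X_g / dilution^(g-1)."""
    return X / dilution_factor ** np.arange(X.size)


def percent_undivided(X, dilution_factor: float = 2.0) -> float:
    """Phi_1: percent of input cells that have not divided.

    Scale-invariant in X (percentages or raw counts are equivalent).
    """
    arr = _as_freqs(X)
    n = _precursors(arr, dilution_factor)
    return 100.0 * n[0] / n.sum()


def phi_series(X, dilution_factor: float = 2.0) -> np.ndarray:
    """Phi_1..Phi_{D+1}; Phi_k drops generations < k and re-applies the formula."""
    arr = _as_freqs(X)
    return np.array(
        [percent_undivided(arr[k:], dilution_factor) for k in range(arr.size)]
    )


def theta_series(X, dilution_factor: float = 2.0) -> np.ndarray:
    """theta_i = 100 - Phi_i (percent division per generation-truncation level)."""
    return 100.0 - phi_series(X, dilution_factor)


def theta_curve(X, dilution_factor: float = 2.0, start_index: int = 1) -> pd.DataFrame:
    """Tidy (i, theta_i) table; ``start_index`` relabels the x-axis origin."""
    th = theta_series(X, dilution_factor)
    return pd.DataFrame(
        {"generation": np.arange(start_index, start_index + th.size), "theta": th}
    )


def proliferation_indices(X, dilution_factor: float = 2.0) -> dict[str, float]:
    """Standard cohort indices derived from per-generation frequencies.

    division_index
        Mean divisions per input precursor: sum (g-1) n_g / sum n_g.
    proliferation_index
        Mean divisions per *divided* precursor: sum (g-1) n_g / sum_{g>=2} n_g
        (0 when nothing divided).
    expansion_index
        Fold expansion of the culture: sum X_g / sum n_g.
    """
    arr = _as_freqs(X)
    n = _precursors(arr, dilution_factor)
    g = np.arange(arr.size)
    divided = n[1:].sum()
    return {
        "division_index": float((g * n).sum() / n.sum()),
        "proliferation_index": float((g * n).sum() / divided) if divided > 0 else 0.0,
        "expansion_index": float(arr.sum() / n.sum()),
    }


@dataclass
class ProliferationSummary:
    """Phi/theta series, indices and binning for one sample."""

    Phi: np.ndarray
    Theta: np.ndarray
    indices: dict[str, float]
    sample_id: str = "sample"
    metadata: dict = field(default_factory=dict)

    @property
    def D(self) -> int:
        return self.Phi.size - 1

    @property
    def phi1(self) -> float:
        return float(self.Phi[0])

    @property
    def n_divisions(self) -> int:
        """Number of observed divisions (max generation - 1)."""
        return self.D


def summarize(
    X, sample_id: str = "sample", dilution_factor: float = 2.0
) -> ProliferationSummary:
    """Compute the full per-sample summary from generation frequencies."""
    if isinstance(X, GenerationFrequencies):
        sample_id = X.sample_id
    phi = phi_series(X, dilution_factor)
    return ProliferationSummary(
        Phi=phi,
        Theta=100.0 - phi,
        indices=proliferation_indices(X, dilution_factor),
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# multiple-comparison correction and condition comparisons
# ---------------------------------------------------------------------------

def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Sidak adjustment.

    Sort raw p ascending; adjusted p_(k) = max_{j<=k} 1 - (1 - p_(j))^(m-j+1),
    clipped to 1, reported in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    stepwise = 1.0 - (1.0 - sorted_p) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def significance_label(p: float) -> str:
    """Figure-legend style labels: * <0.05, ** <0.01, *** <0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    percent_increase_phi1: float
    per_generation: pd.DataFrame  # theta diff + raw/adjusted p per generation
    median_divisions: dict[str, float]
    overall: dict[str, float]  # aggregate test statistic/p
    method: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pg = self.per_generation
        if len(pg) and np.any(pg["p_adjusted"].to_numpy() < pg["p_raw"].to_numpy() - 1e-12):
            raise ValueError("adjusted p below raw p")


def _theta_matrix(summaries: Sequence[ProliferationSummary]) -> np.ndarray:
    width = max(s.Theta.size for s in summaries)
    out = np.full((len(summaries), width), np.nan)
    for i, s in enumerate(summaries):
        out[i, : s.Theta.size] = s.Theta
    return out


def compare_conditions(
    treated: Sequence[ProliferationSummary],
    control: Sequence[ProliferationSummary],
    method: str = "welch",
) -> ComparisonResult:
    """Compare two arms on Phi_1 and per-generation theta.

    The headline effect is the percent increase in mean Phi_1 of treated over
    control. Per-generation theta differences are tested with unpaired
    two-tailed t-tests (Welch by default; ``method="pooled"`` assumes equal
    variance for single-well assays) and Holm-Sidak adjusted. Division
    medians are compared with Mann-Whitney U; an ANOVA helper is available
    separately for >2 arms.
    """
    if not treated or not control:
        raise ValueError("both arms need at least one sample")
    flags: list[str] = []
    phi_t = np.array([s.phi1 for s in treated])
    phi_c = np.array([s.phi1 for s in control])
    if phi_c.mean() == 0:
        raise ValueError("control mean Phi_1 is zero; percent increase undefined")
    increase = 100.0 * (phi_t.mean() - phi_c.mean()) / phi_c.mean()

    th_t, th_c = _theta_matrix(treated), _theta_matrix(control)
    width = max(th_t.shape[1], th_c.shape[1])
    rows = []
    for i in range(width):
        a = th_t[:, i][~np.isnan(th_t[:, i])] if i < th_t.shape[1] else np.array([])
        b = th_c[:, i][~np.isnan(th_c[:, i])] if i < th_c.shape[1] else np.array([])
        diff = (a.mean() if a.size else np.nan) - (b.mean() if b.size else np.nan)
        if a.size >= 2 and b.size >= 2:
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                if np.isclose(a.mean(), b.mean()):
                    stat, p = 0.0, 1.0
                    flags.append(f"generation {i + 1}: zero variance in both arms, p set to 1")
                else:
                    stat, p = np.inf, 0.0
                    flags.append(f"generation {i + 1}: zero variance with unequal means")
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=(method == "pooled"))
        else:
            stat, p = np.nan, np.nan
            flags.append(f"generation {i + 1}: too few samples for a t-test")
        rows.append({"generation": i + 1, "theta_diff": diff, "statistic": stat, "p_raw": p})
    per_gen = pd.DataFrame(rows)
    testable = per_gen["p_raw"].notna()
    adj = np.full(len(per_gen), np.nan)
    if testable.any():
        adj[testable.to_numpy()] = holm_sidak(per_gen.loc[testable, "p_raw"].to_numpy())
    per_gen["p_adjusted"] = adj
    per_gen["label"] = [
        significance_label(p) if math.isfinite(p) else "na" for p in per_gen["p_adjusted"]
    ]

    div_t = np.array([s.n_divisions for s in treated], dtype=float)
    div_c = np.array([s.n_divisions for s in control], dtype=float)
    medians = {"treated": float(np.median(div_t)), "control": float(np.median(div_c))}
    overall: dict[str, float] = {}
    if div_t.size >= 1 and div_c.size >= 1 and (np.ptp(div_t) > 0 or np.ptp(div_c) > 0 or div_t.size * div_c.size > 1):
        try:
            u, p_u = stats.mannwhitneyu(div_t, div_c, alternative="two-sided")
            overall = {"mannwhitney_u": float(u), "p": float(p_u)}
        except ValueError as exc:  # identical constant arms
            flags.append(f"Mann-Whitney undefined: {exc}")
    return ComparisonResult(
        percent_increase_phi1=float(increase),
        per_generation=per_gen,
        median_divisions=medians,
        overall=overall,
        method=method,
        flags=flags,
    )


def anova_conditions(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Ordinary one-way ANOVA across >= 3 aggregate condition groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA helper expects at least 3 condition groups")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return {"F": float(f), "p": float(p)}
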