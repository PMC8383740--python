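"""Simulators with known ground truth: dye-dilution cohorts and NB count matrices.

The dilution simulator follows a synchronous, complete-division model: a
precursor assigned to generation ``g`` contributes exactly
``dilution_factor**(g-1)`` descendant events, each carrying a log10
fluorescence of ``initial - (g-1)*log10(dilution_factor)`` plus one draw of
Gaussian noise, censored below at an autofluorescence floor. Every event
keeps its true generation so downstream estimators can be scored against
truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_io import TRUE_GENERATION_COLUMN, EventTable

__all__ = [
    "DivisionProfile",
    "LabelingModel",
    "CountSimConfig",
    "simulate_cohort",
    "simulate_dose_series",
    "simulate_counts",
    "DEFAULT_CHANNEL",
    "MAX_EVENTS",
]

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL = "CellTrace"
MAX_EVENTS = 5_000_000


@dataclass(frozen=True)
class DivisionProfile:
    """Per-generation precursor fractions; generation 1 means undivided."""

    precursor_fractions: tuple[float, ...]

    def __init__(self, precursor_fractions: Sequence[float]):
        fr = tuple(float(f) for f in precursor_fractions)
        if len(fr) < 1:
            raise ValueError("profile needs at least one generation")
        if any(not math.isfinite(f) or f < 0 for f in fr):
            raise ValueError("precursor fractions must be finite and >= 0")
        total = sum(fr)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"precursor fractions sum to {total}, expected 1")
        object.__setattr__(self, "precursor_fractions", fr)

    @property
    def n_generations(self) -> int:
        return len(self.precursor_fractions)

    def expected_events_per_precursor(self, dilution_factor: float = 2.0) -> float:
        """Sum over generations of p_g * dilution_factor**(g-1)."""
        return sum(
            p * dilution_factor ** g for g, p in enumerate(self.precursor_fractions)
        )


@dataclass(frozen=True)
class LabelingModel:
    """Log10-domain model of label loading, dilution and measurement noise.

    ``inheritance_sd`` accumulates as sqrt(g-1) across divisions and is added
    in quadrature with the initial-label sd and the instrument CV; the
    autofluorescence floor censors (never adds to) the signal.
    """

    log10_initial_mean: float = 4.5
    log10_initial_sd: float = 0.08
    dilution_factor: float = 2.0
    inheritance_sd: float = 0.0
    autofluorescence_floor: float = -np.inf
    instrument_cv_log10: float = 0.04

    def __post_init__(self) -> None:
        if not math.isfinite(self.log10_initial_mean):
            raise ValueError("log10_initial_mean must be finite")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must be > 1")
        for name in ("log10_initial_sd", "inheritance_sd", "instrument_cv_log10"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if math.isnan(self.autofluorescence_floor) or self.autofluorescence_floor == np.inf:
            raise ValueError("autofluorescence_floor must be -inf or finite")

    def generation_mean(self, g: int) -> float:
        return self.log10_initial_mean - (g - 1) * math.log10(self.dilution_factor)

    def generation_sd(self, g: int) -> float:
        return math.sqrt(
            self.log10_initial_sd**2
            + (g - 1) * self.inheritance_sd**2
            + self.instrument_cv_log10**2
        )


def _quota_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n precursors across generations."""
    frac = np.asarray(fractions, dtype=float)
    raw = frac * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_cohort(
    profile: DivisionProfile,
    n_precursors: int,
    labeling: LabelingModel | None = None,
    seed: int | None = None,
    assignment: str = "quota",
    channel: str = DEFAULT_CHANNEL,
    max_events: int = MAX_EVENTS,
    sample_id: str = "simulated",
) -> EventTable:
    """Simulate one labeled cohort; returns log10-domain events with truth.

    With ``assignment="quota"`` (default) precursors are apportioned
    deterministically by largest remainder, so the realized event count
    equals ``sum_g round-share(p_g) * dilution**(g-1)`` exactly;
    ``"multinomial"`` draws the generation split instead.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    labeling = labeling or LabelingModel()
    df = labeling.dilution_factor
    expected = n_precursors * profile.expected_events_per_precursor(df)
    if expected > max_events:
        raise ValueError(
            f"expected event count {expected:.3g} exceeds cap {max_events:.3g}; "
            "reduce n_precursors or the number of generations"
        )
    rng = np.random.default_rng(seed)
    if assignment == "quota":
        counts = _quota_counts(profile.precursor_fractions, n_precursors)
    elif assignment == "multinomial":
        counts = rng.multinomial(n_precursors, np.asarray(profile.precursor_fractions))
    else:
        raise ValueError(f"unknown assignment {assignment!r}")

    gens, fluors = [], []
    for g, n_prec in enumerate(counts, start=1):
        if n_prec == 0:
            continue
        n_ev = int(round(n_prec * df ** (g - 1)))
        mu, sd = labeling.generation_mean(g), labeling.generation_sd(g)
        vals = np.full(n_ev, mu) if sd == 0 else rng.normal(mu, sd, size=n_ev)
        np.maximum(vals, labeling.autofluorescence_floor, out=vals)
        gens.append(np.full(n_ev, g, dtype=int))
        fluors.append(vals)
    gen = np.concatenate(gens) if gens else np.array([], dtype=int)
    fluor = np.concatenate(fluors) if fluors else np.array([])
    order = rng.permutation(len(gen))
    data = pd.DataFrame({channel: fluor[order], TRUE_GENERATION_COLUMN: gen[order]})
    table = EventTable(data, sample_id=sample_id)
    table.transforms[channel] = "log10"
    return table


def scale_undivided(profile: DivisionProfile, multiplier: float) -> DivisionProfile:
    """Multiply the undivided fraction and renormalize the divided remainder."""
    p = np.asarray(profile.precursor_fractions, dtype=float)
    p1 = min(1.0, p[0] * multiplier)
    rest = p[1:]
    if rest.sum() > 0 and p1 < 1.0:
        rest = rest * (1.0 - p1) / rest.sum()
    else:
        rest = np.zeros_like(rest)
        p1 = 1.0
    return DivisionProfile(np.concatenate([[p1], rest]))


def simulate_dose_series(
    base_profile: DivisionProfile,
    concentrations: Sequence[float],
    effect: Callable[[float], float],
    labeling: LabelingModel | None = None,
    n_precursors: int = 10_000,
    seed: int | None = None,
    **kwargs,
) -> list[EventTable]:
    """One cohort per concentration; ``effect`` scales the undivided fraction.

    Requires effect(0) == 1 so a zero dose reproduces the base profile; a
    non-monotone effect map is accepted but logged.
    """
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    if abs(effect(0.0) - 1.0) > 1e-9:
        raise ValueError("effect(0) must equal 1 (null dose leaves profile unchanged)")
    mults = [effect(float(c)) for c in sorted(concentrations)]
    if any(b < a - 1e-12 for a, b in zip(mults, mults[1:])):
        logger.warning("effect map is not monotone non-decreasing in concentration")
    seq = np.random.SeedSequence(seed)
    out = []
    for child, c in zip(seq.spawn(len(concentrations)), concentrations):
        prof = scale_undivided(base_profile, effect(float(c)))
        out.append(
            simulate_cohort(
                prof,
                n_precursors,
                labeling,
                seed=child,
                sample_id=f"dose_{c:g}",
                **kwargs,
            )
        )
    return out


def load_simulation_config(path) -> dict:
    """Read a JSON simulation config into constructor-ready pieces.

    Recognized keys: ``profile`` (list of precursor fractions),
    ``n_precursors``, ``seed``, ``assignment``, ``channel`` and any
    :class:`LabelingModel` field (``log10_initial_mean``, ``log10_initial_sd``,
    ``dilution_factor``, ``inheritance_sd``, ``autofluorescence_floor``,
    ``instrument_cv_log10``). Returns a dict with ``profile``, ``labeling``
    and the remaining keyword arguments for :func:`simulate_cohort`.
    """
    import json
    from pathlib import Path

    raw = json.loads(Path(path).read_text())
    if "profile" not in raw:
        raise KeyError("config missing required key 'profile'")
    lab_fields = {f for f in LabelingModel.__dataclass_fields__}
    lab_kwargs = {k: v for k, v in raw.items() if k in lab_fields}
    rest = {
        k: v
        for k, v in raw.items()
        if k not in lab_fields and k != "profile"
    }
    known = {"n_precursors", "seed", "assignment", "channel", "max_events", "sample_id"}
    unknown = set(rest) - known
    if unknown:
        raise KeyError(f"unrecognized config keys: {sorted(unknown)}")
    return {
        "profile": DivisionProfile(raw["profile"]),
        "labeling": LabelingModel(**lab_kwargs),
        **rest,
    }


@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial count-matrix simulation with planted fold changes."""

    n_genes: int = 1000
    group_sizes: tuple[int, int] = (3, 3)
    baseline_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 counts
    dispersion: float = 0.1
    de_fraction: float = 0.0
    fold_change: float = 1.0
    library_size_factors: tuple[float, ...] | None = None
    paralog_groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or min(self.group_sizes) < 1:
            raise ValueError("n_genes and group sizes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.library_size_factors is not None:
            lsf = tuple(float(x) for x in self.library_size_factors)
            if len(lsf) != sum(self.group_sizes):
                raise ValueError("library_size_factors length must equal total samples")
            if any(x <= 0 for x in lsf):
                raise ValueError("library_size_factors must be positive")
            object.__setattr__(self, "library_size_factors", lsf)
        members = [m for ms in self.paralog_groups.values() for m in ms]
        if len(members) != len(set(members)):
            raise ValueError("paralog groups must have disjoint members")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)


def simulate_counts(config: CountSimConfig):
    """Simulate a gene x sample NB count matrix plus a DE truth table.

    Returns
    -------
    (CountMatrix, pandas.DataFrame)
        The matrix carries gene lengths, two sample groups and the configured
        paralog groups. The truth table has one row per planted gene with its
        fold change (applied to group B); empty when ``de_fraction`` is 0.
    """
    from .expression import CountMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.group_sizes
    named = [m for ms in config.paralog_groups.values() for m in ms]
    n_anon = config.n_genes - len(named)
    if n_anon < 0:
        raise ValueError("more paralog members than genes")
    genes = named + [f"GENE{i:05d}" for i in range(n_anon)]

    lo, hi = config.baseline_mean_log_range
    base_mu = 10 ** rng.uniform(lo, hi, size=config.n_genes)
    lengths_kb = rng.uniform(0.5, 10.0, size=config.n_genes)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    fc = np.ones(config.n_genes)
    fc[de_idx] = config.fold_change
    # half of planted genes go down instead of up
    down = de_idx[rng.random(n_de) < 0.5]
    fc[down] = 1.0 / config.fold_change

    lsf = np.asarray(
        config.library_size_factors
        if config.library_size_factors is not None
        else np.ones(config.n_samples)
    )
    mu = np.empty((config.n_genes, config.n_samples))
    mu[:, :n_a] = base_mu[:, None]
    mu[:, n_a:] = (base_mu * fc)[:, None]
    mu *= lsf[None, :]

    # NB via gamma-Poisson; dispersion alpha: var = mu + alpha*mu^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, scale=mu / shape)
    counts = rng.poisson(lam)

    samples = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    matrix = CountMatrix(
        counts=counts_df,
        gene_lengths=pd.Series(lengths_kb, index=genes),
        sample_groups={s: ("A" if i < n_a else "B") for i, s in enumerate(samples)},
        paralog_groups={k: list(v) for k, v in config.paralog_groups.items()},
    )
    planted = sorted(de_idx)
    truth = pd.DataFrame(
        {
            "true_fold_change": fc[planted],
            "is_de": np.full(len(planted), config.fold_change != 1.0),
        },
        index=[genes[i] for i in planted],
    )
    return matrix, truth
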