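"""Downstream Spo0A~P readouts and rare-event frequency statistics.

Spo0A~P binds its target promoters as an activator or repressor with a
hierarchy set by binding affinity: high-affinity targets (abrB-like
repression) respond at low Spo0A~P, low-affinity targets (spoIIG-like
activation) only near stationary phase.  Transitions to competence are
modeled as an inhomogeneous-Poisson hazard on the comK-channel activity --
raising the average cell's comK expression moves it closer to the
transition threshold and multiplies the hazard -- rather than as an
explicit bistable ComK circuit.

Frequencies of rare events (fluorescent cells per cells counted, spores
per viable count) use exact Clopper-Pearson binomial intervals, which
remain meaningful at zero or one positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, DomainError

__all__ = [
    "ThresholdPromoter",
    "TransitionModel",
    "CountData",
    "FrequencyResult",
    "target_response",
    "simulate_transitions",
    "event_frequency",
    "sporulation_frequency",
    "fold_change",
    "molarity_from_mass_conc",
    "read_count_table",
    "bundled_spore_counts",
]


@dataclass(frozen=True)
class ThresholdPromoter:
    """A Spo0A~P target: Hill response with half-maximal point ``K``."""

    name: str
    mode: str           # "repressed" or "activated"
    K: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("repressed", "activated"):
            raise ConfigurationError(
                f"threshold promoter {self.name}: mode must be 'repressed' or "
                f"'activated', got {self.mode!r}")
        if self.K <= 0:
            raise ConfigurationError(f"threshold promoter {self.name}: K must be > 0")
        if self.hill_n < 1:
            raise ConfigurationError(f"threshold promoter {self.name}: hill_n must be >= 1")


@dataclass(frozen=True)
class TransitionModel:
    """Threshold-proximity hazard for stochastic developmental transitions.

    ``lambda(t) = lambda0 * (A(t) / K_c) ** m`` -- the transition rate grows
    steeply as the driving activity approaches the threshold scale ``K_c``.
    """

    lambda0: float
    m: float = 1.0
    K_c: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ConfigurationError("lambda0 must be >= 0")
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.K_c <= 0:
            raise ConfigurationError("K_c must be > 0")

    def hazard(self, activity) -> np.ndarray:
        a = np.maximum(np.asarray(activity, dtype=float), 0.0)
        return self.lambda0 * (a / self.K_c) ** self.m


@dataclass(frozen=True)
class CountData:
    """Positives out of a total, with an optional plating dilution factor."""

    positives: int
    total: int
    dilution: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.total):
            raise DataError(
                f"{self.label or 'counts'}: need 0 <= positives <= total "
                f"(got {self.positives}/{self.total})")
        if self.dilution < 1:
            raise DataError("dilution factor must be >= 1")


@dataclass(frozen=True)
class FrequencyResult:
    """A percentage with its exact 95% binomial confidence interval."""

    frequency_pct: float
    ci_low_pct: float
    ci_high_pct: float
    positives: int
    total: int


def target_response(spo0a_p, promoter: ThresholdPromoter):
    """Multiplicative Hill factor a Spo0A~P level imposes on a target.

    Repressed targets: ``1 / (1 + (Sp/K)^n)``; activated targets:
    ``Sp^n / (K^n + Sp^n)``.  Accepts scalars or series.
    """
    sp = np.asarray(spo0a_p, dtype=float)
    ratio = np.maximum(sp, 0.0) / promoter.K
    if promoter.mode == "repressed":
        out = 1.0 / (1.0 + ratio ** promoter.hill_n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ratio ** promoter.hill_n
            out = p / (1.0 + p)
        out = np.where(ratio <= 0, 0.0, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def simulate_transitions(time, comk_activity, model: TransitionModel,
                         n_cells: int, seed: int = 0,
                         query_times: Sequence[float] | None = None):
    """First transition times for ``n_cells`` under the activity-driven hazard.

    Each cell transitions at the first event of an inhomogeneous Poisson
    process with rate ``model.hazard(A(t))``: the cumulative hazard is
    integrated on the grid and each cell's transition time solves
    ``H(t) = -ln u`` for an independent uniform draw ``u``.  Returns
    ``(transition_times, counts)`` where ``transition_times`` holds NaN for
    cells that never transition within the run, and ``counts`` is the
    cumulative number transitioned at each of ``query_times`` (defaulting
    to the full grid).  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    time = np.asarray(time, dtype=float)
    haz = model.hazard(comk_activity)
    if haz.shape != time.shape:
        raise DomainError("simulate_transitions: series must share the grid")
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (haz[1:] + haz[:-1]) * np.diff(time))))
    rng = np.random.default_rng(seed)
    targets = -np.log(rng.random(n_cells))
    # invert the (monotone) cumulative hazard
    t_trans = np.interp(targets, cum, time, right=np.nan)
    t_trans[targets > cum[-1]] = np.nan
    if query_times is None:
        query_times = time
    q = np.asarray(query_times, dtype=float)
    finite = t_trans[np.isfinite(t_trans)]
    counts = np.searchsorted(np.sort(finite), q, side="right")
    return t_trans, counts


def event_frequency(positives: int, total: int,
                    confidence: float = 0.95) -> FrequencyResult:
    """Percentage of positives with an exact Clopper-Pearson interval.

    With zero positives the lower bound is 0 and the upper bound is the
    one-sided exact limit (close to the rule-of-three ``3/n`` for large
    ``n``); symmetrically for ``positives == total``.
    """
    counts = CountData(positives=positives, total=total)  # validates
    if total <= 0:
        raise DataError("total must be > 0")
    alpha = 1.0 - confidence
    k, n = counts.positives, counts.total
    if k == 0:
        low = 0.0
        high = 1.0 - alpha ** (1.0 / n)  # one-sided upper bound
    elif k == n:
        low = alpha ** (1.0 / n)
        high = 1.0
    else:
        low = stats.beta.ppf(alpha / 2, k, n - k + 1)
        high = stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return FrequencyResult(
        frequency_pct=100.0 * k / n,
        ci_low_pct=100.0 * float(low),
        ci_high_pct=100.0 * float(high),
        positives=k,
        total=n,
    )


def sporulation_frequency(spores_per_ml: float, viable_per_ml: float) -> float:
    """Heat-resistant (spore) count as a percentage of the viable count."""
    import warnings

    if viable_per_ml <= 0:
        raise DomainError("viable count must be > 0")
    if spores_per_ml < 0:
        raise DomainError("spore count must be >= 0")
    if spores_per_ml > viable_per_ml:
        warnings.warn("spores exceed viable count; possible count inversion")
    return 100.0 * spores_per_ml / viable_per_ml


def fold_change(freq_a: float, freq_b: float) -> float:
    """Ratio of two frequencies; ``freq_b = 0`` gives ``inf`` with a warning."""
    import warnings

    if freq_a < 0 or freq_b < 0:
        raise DomainError("frequencies must be >= 0")
    if freq_b == 0:
        warnings.warn("fold_change: reference frequency is zero (infinite fold)")
        return float("inf")
    return freq_a / freq_b


def molarity_from_mass_conc(mass_mg_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert mg/ml to mM: ``1000 * mass / molar_mass``."""
    if mass_mg_per_ml <= 0 or molar_mass_g_per_mol <= 0:
        raise DomainError("mass concentration and molar mass must be > 0")
    return 1000.0 * mass_mg_per_ml / molar_mass_g_per_mol


def read_count_table(path):
    """Read a count-table CSV in either accepted layout.

    ``label,positives,total`` rows become microscopy-style counts;
    ``label,viable_per_ml,spores_<t>h,...`` rows are plating counts, for
    which per-timepoint sporulation frequencies (%) are appended as
    ``freq_<t>h_pct`` columns.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"label", "positives", "total"} <= cols:
        return df
    spore_cols = [c for c in df.columns if c.startswith("spores_")]
    if "viable_per_ml" in cols and spore_cols:
        for c in spore_cols:
            tag = c.removeprefix("spores_")
            df[f"freq_{tag}_pct"] = 100.0 * df[c] / df["viable_per_ml"]
        return df
    raise DataError(
        f"{path}: expected columns label,positives,total or "
        "label,viable_per_ml,spores_*")


def bundled_spore_counts():
    """The packaged sporulation plating-count table with frequencies."""
    from importlib import resources

    return read_count_table(resources.files("luxpulse") / "data" / "spore_counts.csv")
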