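"""The assay's core statistics: division rate, death rate, fold change.

Division rate.  A cell gated at ``k`` divisions stands for ``2**-k``
cells present at staining, so the generation distribution ``p`` implies
a population expansion of ``1 / sum_k p_k 2**-k`` over the incubation
time ``t``.  Taking log2 (division doubles the population) and dividing
by ``t`` gives the average number of divisions per cell and day:

    d = -log2( sum_k p_k * 2**-k ) / t

Death rate.  Apoptotic-or-dead cells among viable+apoptotic+dead (the
PI-only artifact quadrant is excluded), scaled to per-day by the
detectability window ``w_death`` (cells remain scorable for roughly one
day between apoptosis onset and lysis):

    D = (apoptotic + dead) / (viable + apoptotic + dead) / w_death
    V = 1 - D

Growth.  Division adds ``d`` and death subtracts ``-log2(V)`` doublings
per day, so the net per-day exponent is ``g = d + log2(V)`` and the fold
change over ``t`` days is ``F(t) = 2**(g*t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import (
    GenerationProfile,
    QuadrantCounts,
    auto_threshold,
    classify_quadrants,
    fit_generations,
    quadrant_labels,
)
from .io import EventTable

__all__ = [
    "AssayWindow",
    "RateEstimates",
    "division_rate",
    "death_rate",
    "fold_change",
    "growth_exponent",
    "bootstrap_rates",
    "point_estimates",
    "replicate_summary",
]


@dataclass(frozen=True)
class AssayWindow:
    """Timing assumptions of the assay.

    ``t_days``: incubation between dye staining and measurement (48 h by
    default).  ``w_death_days``: time a dying cell stays scorable
    between apoptosis-marker positivity and lysis (~1 day); it converts
    the observed death fraction to a per-day rate and is deliberately a
    visible knob, since it is an assumption rather than a measurement.
    """

    t_days: float = 2.0
    w_death_days: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_days > 0:
            raise ValueError("t_days must be > 0")
        if not self.w_death_days > 0:
            raise ValueError("w_death_days must be > 0")


@dataclass
class RateEstimates:
    """Point estimates (and optional bootstrap CIs) of the assay statistics."""

    d: float
    D: float
    V: float
    g: float
    F1: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_events: int = 0
    n_replicates: int = 1
    n_boot: int = 0
    n_boot_dropped: int = 0


def division_rate(profile, window: AssayWindow = AssayWindow()) -> float:
    """Average divisions per cell and day from the generation distribution."""
    p = np.asarray(
        profile.proportions if isinstance(profile, GenerationProfile) else profile,
        dtype=float,
    )
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"generation proportions must sum to 1 (got {p.sum():.8f})")
    if (p < -1e-12).any():
        raise ValueError("generation proportions must be non-negative")
    k = np.arange(p.size)
    return float(-np.log2(np.dot(p, 2.0 ** -k)) / window.t_days)


def death_rate(q: QuadrantCounts, window: AssayWindow = AssayWindow()) -> tuple[float, float]:
    """Per-day death rate D and viability rate V = 1 - D.

    Artifact events are excluded; raises when viability reaches zero,
    where the growth model (log2 V) is undefined.
    """
    total = q.viable + q.apoptotic + q.dead
    if total < 1:
        raise ValueError("need at least one viable/apoptotic/dead event")
    D = (q.apoptotic + q.dead) / total / window.w_death_days
    V = 1.0 - D
    if V <= 0:
        raise ValueError("viability zero; growth model undefined (log2 V diverges)")
    return float(D), float(V)


def growth_exponent(d: float, V: float) -> float:
    """Net per-day growth exponent g = d + log2(V) (doublings per day)."""
    if not 0 < V <= 1:
        raise ValueError("viability rate must be in (0, 1]")
    return float(d + np.log2(V))


def fold_change(d: float, V: float, t_days: float) -> float:
    """Predicted fold change of cell number after ``t_days``: 2**((d+log2 V)*t)."""
    if t_days < 0:
        raise ValueError("t_days must be >= 0")
    return float(2.0 ** (growth_exponent(d, V) * t_days))


# ---------------------------------------------------------------------------
# pipeline point estimates and bootstrap
# ---------------------------------------------------------------------------

def point_estimates(
    events: EventTable,
    window: AssayWindow = AssayWindow(),
    k_max: int = 4,
    ag_threshold="auto",
    pi_threshold="auto",
    generations_from: str = "all",
    mu0_init="p99",
    sigma_init: float = 0.3,
) -> tuple[RateEstimates, GenerationProfile, QuadrantCounts]:
    """Run thresholds -> quadrants -> generation fit -> rates on gated events.

    ``generations_from`` selects which events feed the dye deconvolution:
    ``"all"`` (every gated event with positive dye signal, mirroring the
    published gating) or ``"viable"`` (marker-negative cells only, the
    natural choice when the target is the division rate of the surviving
    population).
    """
    ag = events.data["AG_A"].to_numpy()
    pi = events.data["PI_A"].to_numpy()
    t_ag = auto_threshold(ag) if ag_threshold == "auto" else float(ag_threshold)
    t_pi = auto_threshold(pi) if pi_threshold == "auto" else float(pi_threshold)
    quadrants = classify_quadrants(events, t_ag, t_pi)
    D, V = death_rate(quadrants, window)

    ctv = events.data["CTV_A"].to_numpy()
    if generations_from == "viable":
        ctv = ctv[quadrant_labels(events, t_ag, t_pi) == "viable"]
    elif generations_from != "all":
        raise ValueError("generations_from must be 'all' or 'viable'")
    profile = fit_generations(ctv, k_max=k_max, mu0_init=mu0_init, sigma_init=sigma_init)
    d = division_rate(profile, window)
    g = growth_exponent(d, V)
    est = RateEstimates(
        d=d, D=D, V=V, g=g, F1=float(2.0 ** g), n_events=events.n_events
    )
    return est, profile, quadrants


def bootstrap_rates(
    events: EventTable,
    window: AssayWindow = AssayWindow(),
    k_max: int = 4,
    B: int = 1000,
    seed: int = 0,
    ag_threshold="auto",
    pi_threshold="auto",
    generations_from: str = "all",
    mu0_init="p99",
    max_dropped_fraction: float = 0.2,
) -> RateEstimates:
    """Event-bootstrap the full pipeline on one gated sample.

    Resamples events with replacement ``B`` times, refits the generation
    mixture and re-derives the quadrant thresholds on each resample, and
    returns percentile 95% intervals for d, D, V, g and the per-day fold
    change.  Resamples that hit an error state (e.g. EM non-convergence)
    are dropped and counted; more than ``max_dropped_fraction`` dropped
    is an error.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100")
    est, profile, quadrants = point_estimates(
        events, window, k_max, ag_threshold, pi_threshold, generations_from,
        mu0_init=mu0_init,
    )
    rng = np.random.default_rng(seed)
    n = events.n_events
    stats: dict[str, list[float]] = {k: [] for k in ("d", "D", "V", "g", "F1")}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = events.subset(idx)
        try:
            # warm-start each refit from the full-sample peak anchor: the
            # resample cannot shift the ladder placement, only the weights
            b_est, _, _ = point_estimates(
                sample, window, k_max, ag_threshold, pi_threshold, generations_from,
                mu0_init=profile.mu0, sigma_init=profile.sigma_log2,
            )
        except Exception:
            dropped += 1
            continue
        for key in stats:
            stats[key].append(getattr(b_est, key))
    if dropped > max_dropped_fraction * B:
        raise RuntimeError(f"bootstrap dropped {dropped}/{B} resamples")
    ci = {
        key: tuple(np.percentile(vals, [2.5, 97.5]))
        for key, vals in stats.items()
    }
    est.ci = ci
    est.n_boot = B
    est.n_boot_dropped = dropped
    return est


def replicate_summary(estimates: list[RateEstimates]) -> dict[str, tuple[float, float]]:
    """Mean and SD of each statistic across replicate samples (wells)."""
    if not estimates:
        raise ValueError("no replicate estimates given")
    out = {}
    for key in ("d", "D", "V", "g", "F1"):
        vals = np.array([getattr(e, key) for e in estimates], dtype=float)
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out
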