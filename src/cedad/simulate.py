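"""Stochastic birth-death branching-process generator for assay data.

Every cell lives independently.  From birth it draws a Gamma-distributed
inter-division time (shape ``division_time_shape``, mean
``division_time_mean_days``) and, in competition, an exponential waiting
time to apoptosis onset (hazard ``death_hazard_per_day``, optionally
stepping to a second hazard at ``hazard_step_day``).  Whichever fires
first within the assay window wins:

* division replaces the cell by two daughters one generation deeper,
  each carrying half the division-tracking dye (exactly one log2 unit);
* apoptosis onset freezes the lineage and starts a state machine
  live -> apoptotic (marker+/PI-) -> dead (marker+/PI+) -> lysed
  (removed), with fixed-length windows.

At harvest the surviving pool (live + apoptotic + dead) is subsampled to
``n_events_recorded`` events, a configured fraction of debris/artifact
events (marker-/PI+) is mixed in, and fluorescence is emitted:

* dye intensity: log2-normal around ``dye_initial_log2 - generation``
  with spread ``dye_cv_log2`` (halving per division is exact in the mean);
* apoptosis marker and PI: two log10-normal modes separated by
  ``marker_separation_log10``, the positive mode chosen by true state;
* scatter: log-normal singlet cloud, FSC height tightly proportional to
  area (no doublets are generated; see :func:`spike_doublets`).

A single master seed drives one ``numpy`` Generator used in a fixed
order, so identical configs give byte-identical output; count-series
replicates derive child streams from ``(seed, time_index, replicate)``
so each well is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ExtinctPopulationError
from .io import EventTable

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_population",
    "simulate_count_series",
    "spike_doublets",
]

_STATE_NAMES = ("viable", "apoptotic", "dead", "artifact")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated assay.

    Defaults emulate the published workflow: 5e5 founder cells followed
    for a 48 h window with 10,000 events recorded, a Gamma(8) division
    time and a small quiescent (G0-arrested, never-dividing) fraction
    matching the no-division population visible in control samples, a
    low control death hazard, ~1 d visibility each for the apoptotic and
    dead states, and up to four distinct division generations.  The
    division-time mean is calibrated so the realized count-regression
    doubling time of the control is ~21.4 h.
    """

    n_initial: int = 500_000
    duration_days: float = 2.0
    division_time_mean_days: float = 0.80
    division_time_shape: float = 8.0
    quiescent_fraction: float = 0.02
    death_hazard_per_day: float = 0.05
    apoptotic_window_days: float = 1.0
    dead_window_days: float = 1.0
    artifact_fraction: float = 0.03
    dye_initial_log2: float = 16.0
    dye_cv_log2: float = 0.25
    marker_separation_log10: float = 2.0
    marker_sigma_log10: float = 0.25
    ag_negative_mode_log10: float = 2.0
    pi_negative_mode_log10: float = 2.0
    count_cv: float = 0.05
    n_events_recorded: int = 10_000
    max_generation: int = 4
    hazard_step_day: float | None = None
    hazard_after_step: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if not self.duration_days > 0:
            raise ValueError("duration_days must be > 0")
        for name in (
            "division_time_mean_days",
            "division_time_shape",
            "death_hazard_per_day",
            "apoptotic_window_days",
            "dead_window_days",
            "dye_cv_log2",
            "marker_separation_log10",
            "marker_sigma_log10",
            "count_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")
        if not 0 <= self.quiescent_fraction < 1:
            raise ValueError("quiescent_fraction must be in [0, 1)")
        if self.n_events_recorded < 1:
            raise ValueError("n_events_recorded must be >= 1")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")
        if (self.hazard_step_day is None) != (self.hazard_after_step is None):
            raise ValueError("hazard_step_day and hazard_after_step go together")

    @property
    def ag_threshold_true(self) -> float:
        """Generator's own marker threshold (mid-way between modes)."""
        return 10.0 ** (self.ag_negative_mode_log10 + self.marker_separation_log10 / 2)

    @property
    def pi_threshold_true(self) -> float:
        return 10.0 ** (self.pi_negative_mode_log10 + self.marker_separation_log10 / 2)


@dataclass
class SimTruth:
    """Ground truth attached to a simulated sample.

    ``true_generation_proportions`` is the harvest distribution of live
    cells over 0..max_generation divisions (deeper generations folded
    into the last bin); the apoptotic/dead fractions are taken over
    viable+apoptotic+dead, matching the assay's artifact-exclusion rule.
    """

    population_counts: pd.DataFrame
    true_generation_proportions: np.ndarray
    true_fraction_apoptotic: float
    true_fraction_dead: float
    fold_change_realized: float
    per_event_labels: pd.DataFrame
    ag_threshold: float
    pi_threshold: float
    n_initial: int


# ---------------------------------------------------------------------------
# branching-process engine
# ---------------------------------------------------------------------------

_MAX_WAVES = 64


def _onset_waiting_times(birth: np.ndarray, cfg: SimulationConfig, rng) -> np.ndarray:
    """Waiting time from birth to apoptosis onset, piecewise-constant hazard."""
    e = rng.exponential(1.0, birth.size)
    h1 = cfg.death_hazard_per_day
    if cfg.hazard_step_day is None:
        if h1 == 0:
            return np.full(birth.size, np.inf)
        return e / h1
    s = cfg.hazard_step_day
    h2 = cfg.hazard_after_step
    wait = np.empty(birth.size)
    after = birth >= s
    # born after the step: only h2 applies
    wait[after] = e[after] / h2 if h2 > 0 else np.inf
    pre = ~after
    budget = h1 * (s - birth[pre])  # cumulative hazard available before the step
    in_first = e[pre] <= budget
    w_pre = np.empty(pre.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        w_pre[in_first] = (e[pre][in_first] / h1) if h1 > 0 else np.inf
    rem = e[pre] - budget
    if h2 > 0:
        w_pre[~in_first] = (s - birth[pre][~in_first]) + rem[~in_first] / h2
    else:
        w_pre[~in_first] = np.inf
    wait[pre] = w_pre
    return wait


def _run_branching(cfg: SimulationConfig, rng) -> dict[str, np.ndarray]:
    """Simulate all lineages; returns flat per-cell arrays.

    For every cell ever alive: ``birth``, ``generation``, ``live_end``
    (time it stopped being live: division or apoptosis onset, +inf if
    live at harvest) and ``onset`` (apoptosis-onset time, nan if none).
    """
    T_end = cfg.duration_days
    shape = cfg.division_time_shape
    mean = cfg.division_time_mean_days

    births: list[np.ndarray] = []
    gens: list[np.ndarray] = []
    live_ends: list[np.ndarray] = []
    onsets: list[np.ndarray] = []

    wave_birth = np.zeros(cfg.n_initial)
    gen = 0
    while wave_birth.size:
        if gen >= _MAX_WAVES:
            raise RuntimeError("branching process exceeded generation cap")
        n = wave_birth.size
        if math.isinf(mean):
            t_div = np.full(n, np.inf)
        elif math.isinf(shape):
            t_div = np.full(n, mean)  # deterministic inter-division time
        else:
            t_div = rng.gamma(shape, mean / shape, n)
        if cfg.quiescent_fraction > 0 and not math.isinf(mean):
            # cells exiting to G0: never divide, still subject to death
            arrested = rng.random(n) < cfg.quiescent_fraction
            t_div[arrested] = np.inf
        t_onset = _onset_waiting_times(wave_birth, cfg, rng)
        div_at = wave_birth + t_div
        onset_at = wave_birth + t_onset

        divides = (div_at <= T_end) & (div_at < onset_at)
        dies = ~divides & (onset_at <= T_end)

        live_end = np.full(n, np.inf)
        live_end[divides] = div_at[divides]
        live_end[dies] = onset_at[dies]
        onset = np.where(dies, onset_at, np.nan)

        births.append(wave_birth)
        gens.append(np.full(n, gen))
        live_ends.append(live_end)
        onsets.append(onset)

        wave_birth = np.repeat(div_at[divides], 2)
        gen += 1

    return {
        "birth": np.concatenate(births),
        "generation": np.concatenate(gens),
        "live_end": np.concatenate(live_ends),
        "onset": np.concatenate(onsets),
    }


def _live_counts(cells: dict[str, np.ndarray], times: np.ndarray) -> np.ndarray:
    birth = np.sort(cells["birth"])
    end = np.sort(cells["live_end"][np.isfinite(cells["live_end"])])
    started = np.searchsorted(birth, times, side="right")
    stopped = np.searchsorted(end, times, side="right")
    return started - stopped


def _harvest_states(cells: dict[str, np.ndarray], cfg: SimulationConfig):
    """State of every never-divided cell at harvest: 0 live, 1 apoptotic, 2 dead, 3 lysed."""
    T_end = cfg.duration_days
    onset = cells["onset"]
    divided = np.isfinite(cells["live_end"]) & np.isnan(onset)
    state = np.full(onset.size, -1)
    live = ~divided & ~np.isfinite(onset)
    state[live] = 0
    with np.errstate(invalid="ignore"):
        age = T_end - onset
        apo = np.isfinite(onset) & (age < cfg.apoptotic_window_days)
        dead = (
            np.isfinite(onset)
            & (age >= cfg.apoptotic_window_days)
            & (age < cfg.apoptotic_window_days + cfg.dead_window_days)
        )
        lysed = np.isfinite(onset) & (age >= cfg.apoptotic_window_days + cfg.dead_window_days)
    state[apo] = 1
    state[dead] = 2
    state[lysed] = 3
    return state, divided


# ---------------------------------------------------------------------------
# fluorescence emission
# ---------------------------------------------------------------------------

def _emit_events(
    generation: np.ndarray, state: np.ndarray, cfg: SimulationConfig, rng
) -> pd.DataFrame:
    """Emit linear-scale intensities for recorded events.

    ``state`` codes: 0 viable, 1 apoptotic, 2 dead, 3 artifact.
    Artifacts get a broad, dim dye distribution (debris carries no
    defined generation).
    """
    n = generation.size
    is_artifact = state == 3
    ctv_log2 = np.where(
        is_artifact,
        rng.normal(cfg.dye_initial_log2 - 2.0, 1.5, n),
        rng.normal(cfg.dye_initial_log2 - generation, cfg.dye_cv_log2, n),
    )
    ag_pos = (state == 1) | (state == 2)
    pi_pos = (state == 2) | (state == 3)
    ag_log10 = rng.normal(
        cfg.ag_negative_mode_log10 + cfg.marker_separation_log10 * ag_pos,
        cfg.marker_sigma_log10,
        n,
    )
    pi_log10 = rng.normal(
        cfg.pi_negative_mode_log10 + cfg.marker_separation_log10 * pi_pos,
        cfg.marker_sigma_log10,
        n,
    )
    fsc_log10 = rng.normal(5.0, 0.06, n)
    ratio = rng.normal(0.95, 0.015, n)  # FSC_H/FSC_A for singlets
    ssc_log10 = fsc_log10 - 0.5 + rng.normal(0.0, 0.08, n)
    fsc_a = 10.0 ** fsc_log10
    return pd.DataFrame(
        {
            "CTV_A": 2.0 ** ctv_log2,
            "AG_A": 10.0 ** ag_log10,
            "PI_A": 10.0 ** pi_log10,
            "FSC_A": fsc_a,
            "FSC_H": fsc_a * ratio,
            "SSC_A": 10.0 ** ssc_log10,
            "generation": np.where(is_artifact, -1, generation).astype(int),
            "state": np.array(_STATE_NAMES, dtype=object)[state],
        }
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_population(
    config: SimulationConfig, times: Sequence[float] | None = None
) -> tuple[EventTable, SimTruth]:
    """Run one assay: grow the population, harvest, record events.

    Returns the recorded :class:`EventTable` (with truth labels) and the
    :class:`SimTruth` for parameter-recovery checks.  ``times`` selects
    where the live-cell trajectory is reported (default: start and end).

    Raises
    ------
    ExtinctPopulationError
        if no live cell remains at harvest.
    """
    rng = np.random.default_rng(config.seed)
    cells = _run_branching(config, rng)
    state, divided = _harvest_states(cells, config)

    if times is None:
        times = [0.0, config.duration_days]
    times = np.asarray(list(times), dtype=float)
    counts = _live_counts(cells, times)
    pop = pd.DataFrame({"day": times, "live_count": counts})

    n_live = int((state == 0).sum())
    if n_live == 0:
        raise ExtinctPopulationError(
            "population extinct: no live cells at harvest "
            f"(duration={config.duration_days} d, hazard={config.death_hazard_per_day}/d)"
        )

    pool = np.flatnonzero((state >= 0) & (state <= 2) & ~divided)
    pool_state = state[pool]
    pool_gen = cells["generation"][pool]

    live_gen = pool_gen[pool_state == 0]
    K = config.max_generation
    gen_binned = np.minimum(live_gen, K)
    props = np.bincount(gen_binned, minlength=K + 1).astype(float)
    props /= props.sum()

    n_vad = pool.size
    frac_apo = float((pool_state == 1).sum() / n_vad)
    frac_dead = float((pool_state == 2).sum() / n_vad)

    n_events = config.n_events_recorded
    n_artifact = int(round(config.artifact_fraction * n_events))
    n_cells = n_events - n_artifact
    if pool.size >= n_cells:
        take = rng.choice(pool.size, size=n_cells, replace=False)
    else:
        take = rng.integers(0, pool.size, size=n_cells)
    rec_gen = pool_gen[take]
    rec_state = pool_state[take]
    if n_artifact:
        rec_gen = np.concatenate([rec_gen, np.zeros(n_artifact, dtype=int)])
        rec_state = np.concatenate([rec_state, np.full(n_artifact, 3)])
    perm = rng.permutation(rec_gen.size)
    rec_gen, rec_state = rec_gen[perm], rec_state[perm]

    data = _emit_events(rec_gen, rec_state, config, rng)
    table = EventTable(data, source="cedad.simulate", meta={"seed": config.seed})
    truth = SimTruth(
        population_counts=pop,
        true_generation_proportions=props,
        true_fraction_apoptotic=frac_apo,
        true_fraction_dead=frac_dead,
        fold_change_realized=float(_live_counts(cells, np.array([config.duration_days]))[0])
        / config.n_initial,
        per_event_labels=data[["generation", "state"]].copy(),
        ag_threshold=config.ag_threshold_true,
        pi_threshold=config.pi_threshold_true,
        n_initial=config.n_initial,
    )
    return table, truth


def simulate_count_series(
    config: SimulationConfig,
    times: Sequence[float],
    replicates: int,
) -> pd.DataFrame:
    """Simulate destructive cell counting: one independent well per row.

    Each (time, replicate) pair runs its own branching process with a
    child seed derived from ``(config.seed, time_index, replicate)`` and
    reports the live count at that time with multiplicative log-normal
    counting noise of CV ``config.count_cv``.
    """
    times = list(times)
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    arr = np.asarray(times, dtype=float)
    if (arr < 0).any() or (len(arr) > 1 and not np.all(np.diff(arr) > 0)):
        raise ValueError("times must be non-negative and strictly increasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rows = []
    sigma = config.count_cv
    for i_t, t in enumerate(arr):
        for rep in range(replicates):
            child = np.random.default_rng([config.seed, i_t, rep])
            if t == 0:
                live = config.n_initial
            else:
                cfg_t = replace(config, duration_days=float(t), seed=config.seed)
                cells = _run_branching(cfg_t, child)
                live = int(_live_counts(cells, np.array([t]))[0])
            if sigma > 0:
                noise = child.lognormal(-0.5 * sigma**2, sigma)
            else:
                noise = 1.0
            rows.append({"day": float(t), "replicate": rep, "count": live * noise})
    return pd.DataFrame(rows)


def spike_doublets(table: EventTable, fraction: float, seed: int = 0):
    """Append synthetic doublet events for singlet-gate testing.

    Doublets are built by resampling real events and doubling FSC area
    while keeping FSC height (two cells passing the laser together sum
    in area but not in peak height).  Returns the spiked table and a
    boolean mask marking the doublets.
    """
    rng = np.random.default_rng(seed)
    n = table.n_events
    n_doub = int(round(fraction * n))
    idx = rng.integers(0, n, size=n_doub)
    doub = table.data.iloc[idx].copy()
    doub["FSC_A"] = doub["FSC_A"] * 2.0
    doub["SSC_A"] = doub["SSC_A"] * 2.0
    data = pd.concat([table.data, doub], ignore_index=True)
    is_doublet = np.zeros(len(data), dtype=bool)
    is_doublet[n:] = True
    perm = rng.permutation(len(data))
    return (
        EventTable(data.iloc[perm].reset_index(drop=True), source=table.source),
        is_doublet[perm],
    )
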