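# Methods

## The measurement model

One cell sample is stained with a division-tracking dye, incubated with or
without treatment for `t` days (default 2.0), then co-stained with an
apoptosis marker and PI and measured by flow cytometry. Three readouts are
derived:

1. **Division generations.** The dye is partitioned equally between
   daughters, so a cell that divided `k` times carries `2^-k` of the initial
   dye. In log2 intensity space the generations form equally spaced peaks one
   unit apart. `gating.fit_generations` models the positive intensities as a
   `(K+1)`-component Gaussian mixture with means constrained to `mu0 - k` and
   a shared standard deviation, fitted by EM over `(mu0, sigma, weights)`.
   `K = 4` by default: at a ~21 h doubling time, up to four divisions occur
   in 48 h; dimmer events are folded into the last gate.

2. **Death quadrants.** Two thresholds partition the marker/PI plane into
   viable (−/−), apoptotic (+/−), dead (+/+) and artifact (−/+). Values equal
   to a threshold count as positive. The artifact quadrant (debris, or cells
   that lysed between the two stainings) is excluded from all rates.

3. **Rates and growth.** With normalized generation proportions `p` and
   incubation time `t`:

       d = -log2(sum_k p_k 2^-k) / t            [divisions / cell / day]

   The identity behind it: each cell at `k` divisions represents `2^-k`
   founder cells, so `1 / sum p_k 2^-k` is the fold expansion the generation
   distribution implies. The death rate relates apoptotic+dead to all
   non-artifact cells and is scaled to per-day by the detectability window
   `w_death` (default 1.0 d — the assumed span between marker positivity and
   lysis):

       D = (a + d) / (v + a + d) / w_death,   V = 1 - D

   and the growth law is `N(t) = N0 * 2^((d + log2 V) t)`. `V <= 0` is a hard
   error, not a clamp: the growth model is undefined there, and clamping
   would hide assay failure.

Cell-count series are fitted by ordinary least squares of `log2(count)` on
time (`growth.fit_exponential`), which is variance-stabilizing for
multiplicative counting noise and puts the regression slope on the same
doublings-per-day scale as `g`. The slope CI uses the t distribution on
residual degrees of freedom; curve bands are pointwise 95% intervals on the
mean (labelled as such; they are not simultaneous bands). Replicate wells
enter as independent observations. An optional `split_factor` column
multiplies counts before fitting to undo culture splitting.
`growth.compare_segments` fits the exponent over the full range, before and
after a split day (counts on the split day belong to both segments), and
flags a *secondary effect* when the late-segment 95% slope CI lies entirely
below the early one — an operationalization of "the late curve grows
significantly slower", deterministic and configurable.

## The synthetic-data generator

`simulate.simulate_population` runs an independent-cell birth–death
branching process. Per cell, from birth: an inter-division time
`T ~ Gamma(shape, mean/shape)` (shape 8 by default — realistic dispersion
without the exponential law's unrealistically fast early divisions; the
field reports roughly Gamma- or lognormal-shaped cycle times) competes with
an exponential apoptosis-onset time (hazard `death_hazard_per_day`,
optionally stepping to a second value at `hazard_step_day` to model delayed
toxicity). Division spawns two daughters one generation deeper; onset
freezes the lineage (dying cells do not divide) and starts the state
machine live → apoptotic (marker+/PI−, `apoptotic_window_days` = 1.0) →
dead (marker+/PI+, `dead_window_days` = 1.0) → lysed (removed). A
`quiescent_fraction` (default 0.02) of cells never divides: cultured lines
retain a small G0/arrested subpopulation, which is what makes the
"no divisions" gate visibly occupied in control samples — and, importantly,
what anchors the generation ladder (below).

Key defaults and where they come from:

| parameter | default | rationale |
| --- | --- | --- |
| `n_initial` | 5e5 | cells seeded per well in the emulated workflow |
| `duration_days` | 2.0 | 48 h treatment window |
| `n_events_recorded` | 10,000 | events recorded per measurement |
| `division_time_mean_days` | 0.80 | calibrated so the realized count-regression doubling time of the control is 21.0–21.5 h, matching the 20.9–21.6 h measured for the emulated cell line (the asymptotic rate alone misses the newborn-cohort age-structure transient) |
| `death_hazard_per_day` | 0.05 | low spontaneous death of a healthy control |
| `apoptotic/dead_window_days` | 1.0 each | ~1-day detectability assumption |
| `dye_initial_log2` | 16 | bright staining, ~65k a.u. |
| `dye_cv_log2` | 0.25 | realistic within-generation spread (peaks resolvable but overlapping) |
| `marker_separation_log10` | 2.0 | two-decade separation typical of viability dyes |
| `artifact_fraction` | 0.03 | small debris population |
| `count_cv` | 0.05 | duplicate-count precision of an automated counter |

Fluorescence is emitted on a linear scale: dye intensity is log2-normal
around `dye_initial_log2 - generation` (halving per division exact in the
mean), markers are two log10-normal modes, scatter is a log-normal singlet
cloud with FSC height tightly proportional to area. Count series simulate
*destructive* counting: every (time, replicate) pair is an independent
simulation with a child seed derived from `(seed, time_index, replicate)`,
so any replicate is reproducible in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no compensation/spillover between channels, no
autofluorescence drift, no dye toxicity or staining heterogeneity between
cells beyond the log-normal spread, no doublets (a spike-in helper exists
for testing the singlet gate), no cell-cycle phase structure (division times
are i.i.d., not age- or phase-dependent beyond the Gamma law), no density
dependence or medium exhaustion, and drug action is reduced to parameter
changes between configs. Real samples also blur the apoptotic/dead windows
rather than switching states at fixed ages.

## Numerical choices

**EM deconvolution.** Initialisation: `mu0` at the 99th percentile of log2
intensity, `sigma = 0.3`, uniform weights; convergence when the
log-likelihood changes by less than `1e-8` relative, at most 500 iterations
(exceeding them raises, carrying the last parameter state). The M-step is
closed-form for all three parameter groups; the likelihood is monotone
(property-tested). Non-positive intensities are excluded before the log2
transform (arcsinh was rejected because it would break the exact unit
spacing that the halving assumption provides).

**Ladder placement.** Placements of the generation ladder one whole log2
unit apart are separate EM basins, and when a terminal bin is empty two
placements fit the data almost equally well — a spare end component can
even gain ~1–2 nats by catching stray tail events. `fit_generations`
therefore converges EM from the p99 anchor and from that anchor ±1
generation, and accepts a brighter placement only when it wins by more than
5 nats; otherwise the brightest occupied peak is taken as the undivided
generation (the assay's standard convention). The margin was calibrated on
simulated samples of both regimes: spurious tail-capture gains measured
0–2.4 nats, while a genuine undivided subpopulation of even a dozen events
among 20,000 is worth 16–29 nats. When a day-0 reference measurement of the
stained, undivided population exists, pass its median log2 intensity as
`mu0_init` — this is standard dye-dilution practice, skips the placement
search, and is the only safe option when *no* undivided cells remain (see
Limitations).

**Thresholding.** `auto_threshold` estimates a Gaussian-kernel density
(Silverman bandwidth) of `log10(value + shift)` — implemented as a 512-bin
histogram with Gaussian smoothing, identical to a KDE up to binning but
O(n), which matters because the bootstrap re-thresholds every resample. The
threshold sits at the deepest valley between the two most prominent modes;
a unimodal sample falls back to mode + 3 robust SD (treating it as pure
negatives — wrong for pure positives, a documented asymmetry). Constant
input is an error.

**Singlet gate.** FSC area/height ratio within ±2.5 robust SD of the
trimmed (1–99%) median, intersected with the 98% covariance ellipse of the
trimmed log-scatter cloud. Retention below 10% logs a warning but does not
raise.

**Bootstrap.** Percentile 95% intervals over B event-resamples of the full
downstream pipeline (re-threshold, re-classify, refit the mixture). Each
resample warm-starts EM from the full-sample `(mu0, sigma)` — a resample
cannot shift the ladder placement, only reweight it — which makes B = 1000
practical. Resamples hitting an error state are dropped and counted; more
than 20% dropped raises.

**Which events feed the dye fit.** Default `generations_from="all"`
(singlets with positive dye signal), mirroring gating practice on the real
assay. For growth prognosis and parameter recovery, `"viable"` is
recommended: dying cells stopped dividing at apoptosis onset, so including
them depresses `d` and double-counts death that `V` already carries — at a
death rate of 0.4 this moves the 2-day prediction from within 10% of the
realized growth to ~35% below it.

## Problem sizes used in tests and the acceptance script

Parameter recovery and prediction checks use 20,000-event samples
(`dye_cv_log2 = 0.25`, marker separation 1.5 decades) over 10–20 seeds;
bootstrap checks use 2,000–8,000 events at B = 100; secondary-effect
detection uses 2,000-founder count simulations at five time points × 3
replicates, 50–100 runs per arm. These sizes put Monte-Carlo noise well
below every asserted tolerance while keeping the default suite at a few
minutes.

## Known limitations

* **Empty generation-0 bin = unidentifiable ladder.** If literally no
  undivided cells are sampled (fast growth, no quiescent subpopulation),
  no algorithm can tell generation `k` from `k+1` brighter; the dimmest
  consistent placement is chosen by convention. The fix is experimental,
  not algorithmic: measure a day-0 reference and pass `mu0_init`.
* The death-rate scaling by `w_death` assumes dying cells are scorable for
  a fixed, known span; the true span varies by cell line and insult, and
  `D` scales linearly with the error in it.
* The assay cannot distinguish death modalities (late apoptosis vs.
  necrosis both end marker+/PI+), and the quadrant counts inherit any
  marker spillover, which the pipeline does not estimate (an optional
  spillover matrix hook exists in `read_events`).
* Generations beyond `K` are folded into the last gate; with substantial
  mass there, `d` is underestimated — raise `k_max`.
* The growth prognosis extrapolates constant rates; it is exactly the tool
  that *reveals* (via `compare_segments`) when that assumption breaks, but
  it cannot correct for it.
* FCS support is a minimal 3.0/3.1 subset (list mode, float32/float64,
  `$PnN` naming) sufficient for round-tripping this package's own files and
  plain exports; it is not a general FCS implementation.
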