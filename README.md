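# cedad

Simultaneous quantification of **cell division** and **cell death** from a
single flow-cytometry sample, with exponential growth prognosis.

Cell counting and metabolic assays report how a cell population grows, but
cannot say *why* it stops growing: a drug that arrests the cell cycle and one
that kills cells can look identical. This package implements the analysis
behind a combined staining assay that separates the two from one sample of
10,000 events: a division-tracking dye (CellTrace Violet, halving with every
division), an apoptosis marker (Apotracker Green, an annexin V analogue) and
propidium iodide (PI, marking membrane rupture). It is intended for cell
biologists quantifying drug effects in culture and for anyone who needs a
fully synthetic, ground-truthed test bed for dye-dilution analysis.

## The statistics

With `p_k` the fraction of gated cells that underwent `k` divisions during an
incubation of `t` days (from deconvolution of the dye histogram), the
**division rate** (average divisions per cell and day) is

    d = -log2( sum_k p_k 2^-k ) / t

since a cell observed after `k` divisions stands for `2^-k` cells present at
staining. From the marker/PI quadrants — viable (−/−), apoptotic (+/−), dead
(+/+), artifact (−/+, excluded) — the **death rate** per day and the
**viability rate** are

    D = (apoptotic + dead) / (viable + apoptotic + dead) / w,   V = 1 - D

where `w` ≈ 1 day is the window in which a dying cell remains scorable before
lysis. Division and death combine into the net growth exponent and the
predicted fold change of the cell number:

    g = d + log2(V)          F(t) = 2^(g t)          T_double = 24/g hours

so a division rate of 1 doubles the population per day, a death rate of 0.5
halves it, and the two cancel exactly when their magnitudes match.

Because no event-level data are published for the original experiments, the
package ships a stochastic birth–death branching-process simulator
(`cedad.simulate`) that generates labelled cytometry events and cell-count
series with known ground truth; every analysis stage is validated against it.

## Worked example

```python
import numpy as np
import cedad

config = cedad.SimulationConfig(n_initial=50_000, n_events_recorded=10_000, seed=3)
events, truth = cedad.simulate_population(config)

rates = cedad.analyze_events(events, generations_from="viable", bootstrap=200).rates
curve = cedad.prognosis(rates, N0=config.n_initial, times=np.arange(0, 2.5, 0.5))

counts = cedad.simulate_count_series(config, [0, 0.5, 1, 1.5, 2], replicates=3)
fit = cedad.fit_exponential(counts)
```

This prints (see `examples/02_growth_prognosis.py`):

    prognosis exponent g (cytometry) : 1.003 doublings/day
    regression exponent g (counting) : 1.034 (95% CI 0.903-1.166)
    realized 2-day fold change       : 4.03; predicted 4.02

i.e. the exponent measured from a *single* cytometry sample agrees with the
exponent regressed from five independent cell counts, and the predicted
2-day fold change matches the simulator's realized growth within 1%.

The `examples/` directory has one short script per capability:

| script | shows |
| --- | --- |
| `01_simulate_and_rates.py` | gating chain, division/death rates with bootstrap CIs |
| `02_growth_prognosis.py` | growth prognosis vs. independent cell counting |
| `03_secondary_effects.py` | delayed-toxicity detection from segment regressions |
| `04_io_roundtrip.py` | CSV/FCS event I/O, channel auto-mapping, reports |

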