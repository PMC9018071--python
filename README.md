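# queenflux

Single-cell analysis of intracellular ATP dynamics and protein-aggregate
accumulation from time-lapse fluorescence microscopy.

Budding yeast maintains intracellular ATP near 4 mM. In mutants of the
energy-sensing machinery (AMPK/Snf1, adenylate kinase Adk1, the transcription
factor Bas1), single cells undergo sudden transient ATP depletions ("ATP
dips"), irreversible "ATP shifts", or slow (~35 min) oscillations — and cells
that dip subsequently accumulate protein aggregates faster. `queenflux`
implements the computational side of this analysis for users of
excitation-ratiometric ATP biosensors (QUEEN-type, excited at 410/490 nm)
together with an aggregate reporter (Hsp104 fusion):

- **Ratiometry** — per-cell mean ratio R_t = I410_t / I490_t from two-channel
  stacks and label masks, detection of single-frame acquisition errors (one
  channel unusually intense, historically ~1/70 frames) and their repair by
  adjacent-frame averaging, and ratio→mM calibration (linear or Hill).
- **ATP-dynamics classification** — lagged differences
  Δratio(t, l) = ratio_t − ratio_{t−l}; an *ATP dip* is a transient decrease
  > 0.5 ratio units spanning > 2 frames, a *shallow dip* 0.33–0.5, an
  *ATP shift* a > 0.33 decrease that never recovers, and *stable* means no
  such event over ≥ 2× the strain doubling time.
- **Aggregate foci** — maxima whose topographic prominence exceeds a noise
  tolerance (default 4000), with intensities measured in a 3-pixel-diameter
  circle; maximum-intensity projection of z-stacks.
- **Dip → aggregation statistic** — reporter intensity is fit by OLS over the
  pre-dip window; RMSD = sqrt(mean (y_t − ŷ_t)²) is computed *before* the dip
  and over cumulative 30-min windows *after* it, and fold changes
  RMSD_after/RMSD_before quantify accelerated accumulation.
- **Oscillation period** — the lag of the first significant positive-lag peak
  of the sample autocorrelation function, with a multiplicity-corrected 95%
  significance band.
- **Synthetic data** — a generator that emulates all of the above with known
  per-cell ground truth, so the whole pipeline is testable closed-loop without
  real microscopy data.

## Worked example

```python
from queenflux import SyntheticConfig, cohort_classify, gen_cohort
from queenflux.config import CohortMix

config = SyntheticConfig(n_cells=200,
                         mix=CohortMix(stable=0.65, dip=0.25, shallow_dip=0.0, shift=0.10))
cohort = gen_cohort(config, seed=1)
fractions, labels, events = cohort_classify(cohort.ratio_traces, doubling_time_min=288.0)
print(fractions)
```

prints

```
{'stable': 0.65, 'dip': 0.255, 'shallow_dip': 0.0, 'shift': 0.095}
```

— the classifier recovers the generated mixture (65% stable, 35% dip-or-shift)
to within binomial sampling noise; `events` lists every detected depletion
with its onset, depth in ratio units, duration and recovery status. The
`examples/` directory holds one short narrative script per capability
(simulation+classification, ratiometry QC, the dip→RMSD statistic, period
estimation, foci detection, the full pipeline).

A command-line front end mirrors the library:

```sh
queenflux run --seed 42 --out out/           # full pipeline on synthetic data
queenflux ratio --channels ch.csv --out traces.csv
queenflux classify --traces traces.csv --out labels.csv
queenflux foci --stack reporter.tif --mask mask.tif --tolerance 4000 --out foci.csv
```

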