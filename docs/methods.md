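# Methods

This note documents the models, numerical choices and limitations behind
`queenflux`. It complements the API docs: nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Ratiometric ATP quantification

The sensor is excited at 410 nm (ATP-sensitive) and 490 nm (reference); the
per-frame ratio of mean in-cell intensities is the cell's ATP readout. The
ratio is oriented with the ex410 channel in the numerator so that it
increases with ATP; the orientation is a convention of this package (the
underlying measurement only fixes it up to inversion) and is configurable by
swapping channels. The ratio is invariant to any gain common to both
channels, which propagates to every downstream quantity (classification,
folds, periods); this invariance is property-tested.

**Calibration.** The ratio→mM map is instrument-specific and user-supplied.
Two forms ship: a linear map (default slope 4, intercept 0, so the baseline
ratio 1.0 corresponds to the ~4 mM resting ATP level of budding yeast) and a
Hill form r(a) = r_min + (r_max − r_min)·aⁿ/(Kⁿ + aⁿ) inverted analytically.
Both are checked for strict monotonicity on a grid at construction and for
round-trip error < 1e-9.

**Acquisition-error QC.** Occasional single-frame exposure failures make
exactly one channel unusually intense. Each channel is compared to its
running median (centred 7-frame window); a frame is anomalous when the
*positive* deviation exceeds 5 robust SDs (MAD × 1.4826). Only frames
anomalous in exactly one channel are flagged: a genuine ATP change moves the
sensitive channel *down* over several frames, and a common-mode glitch moves
both channels and leaves the ratio intact, so neither is flagged. Flagged
ratios are replaced by the mean of the neighbouring frames; flagged edge
frames copy the nearest valid neighbour, and runs of adjacent flags are
repaired outside-in with a warning. At the emulated error rate (1/70 frames,
8-SD spikes) this yields recall ≥ 99% with a false-positive rate well below
1% per frame (measured by the acceptance script).

## ATP-dynamics classification

The classifier intentionally mirrors fixed-threshold rules rather than
learned changepoints, because the class definitions *are* thresholds on the
ratio scale: dip = recovered decrease > 0.5 ratio units spanning more than 2
frames (i.e. ≥ 3 frames); shallow dip = recovered decrease in 0.33–0.5;
shift = decrease > 0.33 with no recovery within the observation window;
stable = no qualifying event over ≥ 2× the strain doubling time (defaults:
3.6 h wild type, 4.8 h for the dip-prone double mutant). Thresholds apply on
the ratio scale, not mM.

The event detector needs two quantities the definitions leave open:

- **Baseline**: running median of the 5 preceding frames, frozen when the
  event opens (so a shifted cell's baseline does not chase the new level).
- **Entry/exit**: an event opens when the ratio falls more than 0.2 units
  below baseline (4σ at the emulated noise level, low enough to catch
  every ≥ 0.33 event) and closes as recovered when it returns above
  baseline − 0.1 × depth.

Depth is baseline-to-nadir, with the nadir taken as the minimum of the
centred 3-frame mean over interior event frames (the raw minimum for 1–2
frame events). On plateau-shaped events this is exact — noiseless injected
dips are recovered with zero depth and duration error — while suppressing
the single-frame noise minimum on real traces, which would otherwise bias
shallow-dip depths across the 0.5 boundary.

A recovered decrease deeper than 0.5 but spanning ≤ 2 frames exceeds the
shallow threshold but fails the dip duration requirement; it is graded
shallow dip. When several event classes co-occur in one cell the label
precedence is dip > shift > shallow dip (cohort fractions pool dip and
shift, so precedence only affects sub-labels). Event-free traces shorter
than 2× doubling time are "indeterminate_stable" and excluded from
fractions.

## Aggregate foci

Foci are local maxima whose topographic prominence — peak height above the
highest saddle connecting it to any higher peak, 8-connected — exceeds the
noise tolerance (default 4000 camera units). This reproduces the
noise-tolerance semantics of interactive FindMaxima-style detectors.
Prominence is computed exactly by a union-find sweep over pixels in
decreasing intensity order; ties break deterministically toward the smaller
flat index, a connected equal-value plateau counts once at its rounded
centroid, and the globally highest peak is measured against the image
minimum (so a uniform image has no foci). The implementation is
property-tested against an independent threshold-descent oracle on hundreds
of random images.

Focus intensity is the mean over the 3-pixel-diameter circle centred on the
peak, rasterized as the centre pixel plus its 4-neighbours (the 5-pixel
"plus" used by ImageJ-style oval measurement at diameter 3); at image
borders only in-bounds pixels contribute and the focus is flagged. When
z-stacks are supplied, detection runs on maximum-intensity projections.

## The dip→aggregation RMSD statistic

In cells with stable ATP the mean reporter intensity rises linearly
(emulated Pearson r ≈ 0.99). For a cell with a dip at frame k, intensity
over [0, k) is fit by ordinary least squares (the fit is refused when the
pre-dip span is below 92 min, a span under which the linear baseline is not
considered established); RMSD about that line is computed *before* (over
[0, k)) and over cumulative windows *after x h* (frames with
0 < t − t_k ≤ x hours, 30-min steps to a 3-h horizon). Fold change =
RMSD_after / RMSD_before; the maximum fold within the horizon is the
per-cell summary. Windows truncated by the end of the trace are flagged
partial and later windows (which would duplicate the truncated one) are not
reported. For stable cells the RMSD is computed over the full span about a
full-span fit.

**The null is not 1.** Even with no post-dip change, extrapolating the OLS
line inflates out-of-window residuals: at time t the prediction variance is
σ²(1 + 1/n + (t − t̄)²/Sxx), while the in-window RMSD underestimates σ by
√(1 − 2/n); small post-dip windows additionally make the max-over-windows
statistic right-skewed. `expected_null_fold` returns the resulting expected
after/before ratio. It is used in two places: the synthetic generator
subtracts it in quadrature when calibrating the planted acceleration, and
tests of "no acceleration" compare cohort folds against this expectation
rather than against literal 1 — testing against 1 would reject the true
no-acceleration model with near certainty at cohort sizes of ~100.

## Oscillation period

The sample ACF (statsmodels, optionally linearly detrended — off by default
for ratio traces, recommended for trending aggregation traces) is scanned
for the first strict local maximum at positive lag (ties toward the smaller
lag) that is positive and exceeds the significance band; its lag × frame
interval is the period, and absence of such a peak is a valid "no period"
result (zero-variance traces short-circuit to it). Because the peak is
searched over every candidate lag rather than chosen by eye, the per-lag
level is Šidák-corrected, α' = 1 − (1 − α)^(1/m) over the m scanned lags;
with the plain per-lag 1.96/√T band, white-noise traces would show a
spurious significant peak in a large fraction of cells. The per-lag 95%
band is still reported on the ACF itself for plotting. On a 4-min frame
grid a 35-min oscillation estimates as 36 min (lag 9); period resolution is
one frame interval.

## Synthetic generator

The generator's defaults are the study conditions the analysis targets:
200 cells × 150 frames at 4-min intervals (10 h), baseline ratio 1.0
(≡ 4 mM), i.i.d. Gaussian ratio noise σ = 0.05, deep dips drawn from
0.56–0.85 ratio units and shallow dips from 0.36–0.44 (both kept clear of
the 0.5 boundary so that truth labels are well-defined under noise), dip
duration ~15 min (3–5 frames), dip count per dip-cell Poisson with rate
0.1/h (at least one), unsynchronized 35-min oscillations of amplitude 0.15
(SNR 3), acquisition errors at 1/70 frames with 8-SD single-channel
positive spikes, reporter intensity rising at 2 units/min with noise set
from the target correlation (r = 0.99), and a post-dip acceleration
calibrated so the expected maximum RMSD fold within 3 h equals the target
(default 5.6), with a unit-mean lognormal (σ = 0.25) per-cell factor.

Depletion events are rectangular: the drop completes within one frame
(the imaging cadence cannot resolve the few-minute descent), holds the
nadir, and recovers in one step or never. The post-dip acceleration is a
linear ramp in the residuals scaled as Δ·√3·(t − t_k)/H with
Δ² = σ²·max(f² − ν², 0) (f the target fold, ν the null inflation above);
the real mechanism (nucleated aggregate growth) is not modelled — only the
statistic's magnitude is.

Image rendering places non-overlapping disk cells, gives the reference
channel a constant level and the sensitive channel ratio × that level (so
per-cell mean ratios reproduce the generating trace exactly in the
noiseless case), renders foci as Gaussian spots (σ = 1.5 px, amplitude
10⁴) on a cytoplasmic background, and optionally adds Poisson + Gaussian
pixel noise. Z-stacks place foci in the central slice so projection
recovers the single-plane image.

**What passing closed-loop tests does not show**: the generator has no cell
division, motion, photobleaching, focus drift, segmentation error, spatial
noise correlation, or non-stationary baselines; real-data performance
depends on upstream segmentation quality and on the calibration constants,
neither of which this package estimates.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
caller; identical (config, seed) reproduce every CSV/JSON byte-for-byte,
and the test suite pins an end-to-end reference report. Test and
acceptance problem sizes (200-cell cohorts, 100-cell fold cohorts, 50-seed
period grids, 200 random images for the prominence oracle) were chosen so
the statistical assertions have comfortable margins while the whole suite
runs in well under a minute of compute per file.

## Known limitations

- The "second peak" period rule reads the first positive-lag ACF peak as
  the period; for strongly asymmetric waveforms the dominant peak may sit
  at a harmonic.
- Dip detection freezes the baseline at entry; slow baseline drifts within
  an event are attributed to the event.
- Foci are not tracked across frames, and focus–granule colocalization is
  out of scope.
- Welch/Dunnett-style hypothesis testing is deliberately not reimplemented;
  the per-cell tables are the analysis-ready input for any stats package.
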