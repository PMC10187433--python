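# Methods

## The hyperoxidation switch

The deterministic core is a five-state mass-action model of a single
effective 2-Cys PRDX pool and extracellular-bolus H2O2 (equations in the
README).  Time is in minutes, H2O2 in uM, thiol states are fractions.
The model realizes four arrows of the PRDX redox cycle -- oxidation to
sulfenic acid (`k_ox`), disulfide resolution (`k_ss`) and thioredoxin
recycling (`k_red`), hyperoxidation (`k_hyp`), and sulfiredoxin repair
(`k_srx`) -- plus H2O2 clearance proportional to the non-hyperoxidized
pool.  The clearance feedback is what converts a ~6x dose range into a
strongly graded response: high doses suppress their own removal while
the pool is hyperoxidized.

Whether the FOXO1-activating hyperoxidation target is PRDX1 itself or a
PRDX1-dependent relay partner is left open; the model treats one
effective pool and does not adjudicate.

### Default rate constants

| parameter | value | units | role |
|---|---|---|---|
| k_ox | 0.005 | /uM/min | SH + H2O2 -> SOH |
| k_ss | 0.6 | /min | SOH -> disulfide |
| k_red | 0.3 | /min | disulfide -> SH (thioredoxin) |
| k_hyp | 0.004 | /uM/min | SOH + H2O2 -> SO2H |
| k_srx | 0.0022 | /min | SO2H -> SOH (SRXN1) |
| k_clear_cell | 0.06 | /min | PRDX-dependent H2O2 clearance |
| k_clear_base | 0.002 | /min | PRDX-independent clearance |
| theta_on / theta_off | 0.55 / 0.40 | – | FOXO1 phase entry/exit on `h` |
| tau_f | 5 | min | FOXO1 shuttling relaxation |
| tau_p53 | 60 | min | FOXO1 exit -> p53 onset delay |

These are package defaults calibrated once so the dose presets reproduce
the qualitative single-cell phenomenology (see "Calibration"), not
literature rate measurements.  With them, the hyperoxidized fraction
peaks at 0.32 / 0.61 / 0.77 / 0.99 for 50 / 80 / 100 / 300 uM, the phase
window opens within 30 min at ≥80 uM, and its length grows from ~4 h at
80 uM to ~17 h at 300 uM.

Hysteresis (`theta_off < theta_on`) prevents chatter near the threshold.
Perturbation presets are pure parameter maps: `prdx1ko` scales
`prdx_scale` by 0.25 (clearance loss shifts activation to >=40 uM),
`j14` scales `k_srx` by 0.05 (phases fail to close within the movie),
`srxn1oe` scales `k_srx` by 4 (minimal activating dose rises from 80 to
100 uM), `conoidina` scales `k_ox` and `k_ss` by 0.2.

### Integration

Classical fixed-step RK4 with 10 equal substeps per 1-min output step.
The initial oxidation burst at 300 uM has rates ~1.5/min, too fast for a
bare 1-min step; substepping keeps the scheme explicit, deterministic,
and within 2.3e-5 of a 100x-finer single-step reference in every state
component over 24 h (the suite asserts <= 1e-3).  Mass conservation
holds to ~1e-15.

## The generative simulator

Cells share one deterministic redox trajectory per dose; per-cell
variability enters through:

* threshold jitter – `theta_on` scaled by N(1, 0.1) per cell (ratio
  `theta_off/theta_on` preserved).  This creates the dose-dependent
  responder fraction: ~0% at <=60 uM, ~84% at 80 uM, ~100% at >=100 uM.
* repair-capacity scale – the phase duration is multiplied by a
  lognormal factor (sigma = 0.4, mean 1).  This spreads nuclear-residence
  times at a fixed dose (as single-cell heat maps show) and gives the
  5-h snapshot at 80-100 uM its two coexisting populations: early-exit
  cells already past p53 onset, late-exit cells still FOXO1-nuclear.
* p53 waveform – on its onset (exit + tau_p53 + N(0, 10 min) jitter,
  clipped at 3 SD so onset always follows exit; or 20 min after t = 0
  with probability dose/(dose+15 uM) when no phase opens), p53 steps to
  an elevated floor (35% of amplitude) and then either oscillates
  (raised-cosine train, period 330 min – a free default, never an
  acceptance value) or ramps to a sustained plateau at 2x the oscillatory
  amplitude.  The onset step is abrupt relative to the 20-min frame so
  run-length onset detection lands within one frame of the truth.
  Per-cell amplitude is lognormal (sigma = 0.25).  The sustained-mode
  probability is a logistic in the cell's effective dose
  (dose x repair scale; midpoint 140 uM, width 45 uM), so weak-repair
  cells couple long FOXO1 phases, sustained p53, and death.
* death – hazard lambda(t) = death_mult · (a·[in phase]·elapsed +
  b·(p53 − 250)+), a = 3e-7 /min^2, b = 3e-6 /(a.u.·min).  The p53 arm
  acts on the excess above a high threshold so deaths strike cells whose
  p53 has climbed to sustained levels; a linear p53 arm was tried and
  rejected because truncation at death then makes dying cells' observed
  maximum p53 lower than survivors' and enriches dying cells for short
  phases – the opposite of the observed fate associations.  Cumulative
  hazard is integrated on the frame grid and inverted against a unit
  exponential; frames after death are missing.
* measurement noise – multiplicative lognormal (sigma = 0.1) on
  trajectory frames and snapshot readouts; FOXO1 nuclear fraction
  clipped to [0, 1]; gamma-H2AX is a saturating Hill function of dose
  (base 100, max fold 4, half-dose 150 uM) with sigma = 0.2 noise.

Sampling is every 20 min for 24 h.  Snapshot populations are latent
trajectories read out at t_fix = 300 min; the death process is not
applied there (fixation precedes most deaths, and it keeps population
sizes exact).  All generators are driven by numpy Generators seeded from
explicit seeds or named substreams of one master seed, so identical
seeds give bitwise-identical tables.

### Calibration

Death-hazard multipliers are calibrated per dose by bisection against a
50,000-cell Monte-Carlo death fraction (common random numbers make the
fraction monotone in the multiplier), targeting the anchor percentages
at 50/80/100/300 uM and linear interpolation in dose elsewhere; the
resulting table is frozen in `redoxtf.params.DEFAULT_DEATH_MULT` and
regenerable with `scripts/calibrate_defaults.py`.  Re-simulation at an
independent seed reproduces 1.0/11.2/34.1/98.0% at 50/80/100/300 uM.

## Analysis stages

* quantify – per-nucleus mean intensity and a 3-px cytoplasmic ring
  (morphological dilation minus all nuclei; contested pixels to the
  nearer nucleus centroid; mean, not median, intensity).  Nuclear
  fraction nuc/(nuc+ring) is bounded in [0,1]; the unbounded nuc/cyto
  ratio was rejected.  The renderer constructs intensities so the
  noise-free fraction is exactly recoverable; under Poisson noise the
  mean absolute error is <~0.001 at the default geometry.
* gating – cutoffs are the q = 0.99 quantiles of an untreated control's
  FOXO1 nuclear fraction and log10 nuclear p53 (mean + 3 SD available as
  an alternative); activity is strict inequality, so a cell exactly at a
  cutoff is inactive.  Labels agree with simulator ground truth at ~97%
  pooled over doses (transition-band cells around t_fix dominate the
  errors).
* dynamics – entry/exit/onset are starts of >= 2-consecutive-frame runs
  (one noisy frame cannot toggle an event); onset uses baseline mean +
  3 SD over the first 3 frames, falling back to a +20% relative rule for
  degenerate baselines.  Phases open at movie end or death are censored,
  not assigned exits.  Heat-map rows sort ascending by duration with
  phase-less cells first and death-censored cells last (by death time);
  how the original displays placed dying cells is not stated, so this
  rule is the package's own.
* oscillation – sample ACF (statsmodels) of the linearly detrended,
  death-truncated p53 series (>= 12 observed frames); the oscillation
  score is the ACF value at the first positive local maximum in a
  260-400 min window, 0 if none.  Pooled group ACFs carry a 1000-sample
  cell-bootstrap 95% band.  Fate comparisons use two-sided Mann-Whitney
  rank tests (the original comparisons name no test).

## What the synthetic data do and do not show

The generator encodes the population-level regularities the analyses
must recover: dose-gated mutually exclusive activation, the two-phase
schedule with a 60-min exit-to-onset delay, dose-increasing phase
duration and death, oscillatory-vs-sustained p53 with fate coupling, and
perturbation shifts in the expected directions.  Passing tests therefore
demonstrate that the analysis stack recovers known ground truth at
realistic noise, sampling, and sample sizes – not that the rate
constants are biologically measured values.  Real microscopy adds
segmentation/tracking errors, photobleaching, illumination bias,
mitosis and migration, none of which are modelled; masks here are
ground truth by construction.  Responder fractions per dose are encoded
only as a qualitative ordering; no quantitative per-dose responder
fractions are assumed.  The p53 period (330 min) is a configurable default,
not a fitted value; cell-density dependence of the dose response is not
modelled.

## Numerical choices and degenerate inputs

Strict inequality at gating cutoffs (constant controls classify nothing
active); ties in heat-map ordering break by cell id; ACF of a constant
series raises a degenerate-series error rather than returning NaN;
onset detection with zero baseline SD switches to the relative rule and
records it; exit alignment requires >= 10 cells with defined exits;
fraction measures with zero nucleus and ring intensity raise an
undefined-measure error; the death-calibration bisection reports
unreachable targets instead of clamping.
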