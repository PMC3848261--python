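# Methods

This note documents the models implemented in `isograd`, the defaults and
the numerical choices, and what the synthetic data do and do not emulate.

## Isocratic retention model

Retention of each analyte under isocratic elution at competing-ion
concentration *c* (mM) is modeled as

    log10 k = a0 + a1·log10 c + a2·log10² c,    k = (tR − t0)/t0 .

The quadratic term is an empirical correction to the linear solvent-strength
model; it absorbs secondary retention mechanisms at the cost of one extra
coefficient. All logarithms are base 10 (the standard chromatographic
convention). Fitting is ordinary least squares of log10 k on
(1, log10 c, log10² c); R² is reported on the fitted (log k) scale. At
least three distinct concentrations are required; the packaged system was
calibrated at five (2, 26, 50, 74, 98 mM). Retention times at or below the
void time are rejected — they would imply k ≤ 0.

Each peak carries three independent models (50%-height fronting point,
apex, 50%-height tailing point), so a predicted peak provides its own
half-height width w = t_tail − t_front.

Caveats of the quadratic form: with a1 > 0 the fitted curve has a retention
*maximum* at log10 c = −a1/(2·a2). For three of the packaged sugars
(fucose, melibiose, raffinose) that maximum falls at 2.3–4.6 mM, inside the
calibration range but below the 5-mM edge of the optimization domain.
Retention is therefore guaranteed monotone-decreasing in eluent strength
only on [5, 95] mM, which is one reason the gradient domain starts at 5 mM.

## Gradient elution integral

A gradient program is piecewise linear between nodes over a 30-min horizon
and holds the terminal concentration indefinitely afterwards. The gradient
retention time solves

    t0 = ∫₀^(tR − t0) dt / k[c(t)]

by a first-order march: time is cut into steps of dt (default 0.01 min,
finer than the 1-Hz data rate of the underlying measurements), k is taken
constant over each step at the mean of its boundary values, and the sum
S = Σ dt/k̄ accumulates until it crosses t0. The crossing is interpolated
linearly within the final step. Because the post-horizon eluent is
constant, an analyte still retained at the horizon is finished in closed
form (remaining time = (t0 − S_horizon)·k_hold); the march never needs to
run past the horizon. A cap of 10× the horizon declares no-elution. For a
constant profile the scheme is exact (the averaged k equals the true k), so
the gradient solver reduces to the isocratic closed form up to the crossing
interpolation (< 2·dt). Convergence in dt is first order.

No dwell-volume (gradient-delay) correction is applied: c(t) is the
programmed concentration at time t from injection. Negative gradient
segments are allowed; node concentrations outside the configured bounds are
rejected at profile construction (optimizers clamp instead).

## Peak shape

Peaks are drawn with the generalized logistic density

    f(t) = (C/B)·e^((A−t)/B) / (1 + e^((A−t)/B))^(C+1),

which integrates to one, is unimodal with mode A + B·ln C, and reduces to
the symmetric logistic at C = 1. A detector trace is h(t) = SF·f(t), the
stretching factor SF being the peak area. The density is evaluated in log
space (softplus form), stable for |A − t|/B beyond ±500.

(A, B, C) are recovered from the three predicted times by exploiting scale
invariance: the half-height asymmetry ratio (t_tail − t_apex)/(t_apex −
t_front) depends on C alone and is solved by Brent root bracketing on
ln C ∈ [ln 1e−3, ln 1e3]; B then scales the unit-width half-height span to
the requested one, and A follows from the mode condition. Half-height times
are matched on the density itself — the uniform scaling by SF cannot move
half-height crossings.

An intrinsic limitation: as C → ∞ the density approaches a Gumbel shape
whose tailing/fronting half-width ratio saturates at ≈ 1.4823 (and → 0 as
C → 0). Peaks more asymmetric than that admit no solution and raise a
no-solution error. The packaged arabitol peak at 2 mM (ratio ≈ 2.4) is such
a case; `render_chromatogram(..., skew_fallback=True)` — used by the CLI —
draws such peaks as symmetric logistics matched to the apex and total
half-height width instead of failing.

The stretching factor of a predicted peak is the isocratically measured
peak area interpolated (linearly, clamped at the table ends) at the eluent
concentration present when the peak apex elutes. Peak area falls with
eluent concentration under amperometric detection; areas only affect
rendered traces, never retention, resolution, or the optimizers.

## Criterion function and the acceptability rule

Adjacent peaks in predicted elution order are scored with
Rs = 1.18·Δt_apex/(w₁ + w₂); a program is condensed to

    CF = (1/ΣRs)^α · tA^β ,

minimized by the optimizers. Defaults α = 1, β = 2 (integer weights; the
time term must outweigh the resolution term for acceptable outcomes).
t_A is the apex time of the last-eluting analyte.

Feasibility has two parts. A program whose last analyte elutes after the
30-min window is always excluded. The optimizers additionally exclude, by
default, programs with any adjacent pair below Rs = 3 (`rs_threshold=3.0`;
a deliberately strict overlap margin for model-based predictions — common
practice accepts 1.5–2). This acceptability rule is essential: the raw CF
is minimized by saturating the eluent at 95 mM, compressing the run to
~10 min with the last pair at Rs ≈ 2 — with the rule, both optimizers
instead converge onto the separation boundary, the last pair pinned at
Rs ≈ 3.00 and the last apex near 19 min. Set `rs_threshold=None` for the
raw criterion.

Excluded programs carry an infinite CF sentinel in reported scores. For
search purposes the batch scorer also provides a graded value: feasible
candidates keep their CF; infeasible ones rank behind every feasible one
by 1e9 + (total Rs shortfall + horizon overrun), and structurally invalid
ones (no elution, inverted markers) behind those at 1e12. A flat infinite
plateau would strand a simplex started in an infeasible region (the default
50-mM isocratic center is overlap-infeasible); the graded value preserves
the exclusion semantics while giving the search a direction.

## Nelder-Mead simplex

Factors are the concentrations at NF equidistant time nodes (one factor =
isocratic elution). The initial simplex is the regular-simplex subset of a
Doehlert lattice: NF+1 mutually equidistant vertices with edge length equal
to the characteristic concentration interval Δc, centered on the isocratic
central point (default 50 mM, the domain midpoint) — Nelder-Mead needs
exactly NF+1 points, not the full NF²+NF+1 Doehlert mesh. Moves use the
standard coefficients (reflection 1, expansion 2, contraction 0.5) plus a
shrink toward the best vertex (0.5) when contraction fails; reflected and
expanded points are clamped coordinate-wise to [5, 95] mM to keep the
simplex inside the domain without degenerating. Termination: total absolute
vertex movement between consecutive iterations < 1e-15, or 5000 iterations.
The search is fully deterministic.

Behavior on the packaged system: under the raw criterion every low-factor
(NF = 2, 3) search collapses onto a constant-concentration program at the
upper bound — the raw optimum — regardless of Δc or center; under the
acceptability rule the searches end at different boundary solutions
depending on (NF, Δc), with best-CF values differing by well over 5%
(local-minimum behavior characteristic of sequential searches on this
surface). The 5-factor, 15-mM configuration ends well separated with the
last apex near 18.9 min.

## Genetic algorithm

Chromosomes are 11 integer genes (mM at t = 0, 3, …, 30 min) on [5, 95].
One run: 100 random units are valued, the worst 70% removed once (leaving
30 parents, hence a 330-gene newborn pool); each cycle pairs the parents
randomly into 15 disjoint pairs, produces 30 offspring by uniform crossover
(complementary random masks, two parents – two descendants), mutates a
fixed number of distinct gene positions chosen without replacement across
the whole offspring pool (default 60 of 330 = 18.2%; each redrawn uniformly
from [5, 95]), values the offspring, merges them with the parents and
removes the worst 50%. Ties in the culls break by unit index (stable sort)
for reproducibility. The best CF is recorded after each of the 200 cycles;
the best unit always survives the elitist merge, so the history is
non-increasing. The *threshold cycle* is the first cycle after which the
best-CF improvement stays below 1e-12 for the remainder of the run. A
seeded generator drives every stochastic step; identical seeds give
bit-identical runs.

Integer coding has a polishing consequence: mutation redraws a gene
uniformly over all 91 values, so the probability of hitting one exact
target value at one position is small, and 200-cycle runs on a strict
quadratic test function end within ±1–2 of the optimum per gene rather
than exactly on it. On the chromatographic surface this is immaterial —
the optimum sits on the Rs = 3 acceptability boundary, not at an isolated
lattice point.

## Synthetic data

The generator draws apex coefficients from ranges bracketing the packaged
system (a0 ∈ [−0.3, 2.0], a1 ∈ [−0.05, 0.4], a2 ∈ [−0.35, −0.02]), derives
fronting/tailing models by shifting a0 down/up by 0.005–0.03 (which
preserves the marker ordering at every concentration), and emits five-point
isocratic tables at 2–98 mM with Gaussian noise of configurable σ on
log10 k. Area tables decrease linearly by 60% across the calibration range
from a per-analyte scale — they reproduce the qualitative trend (area falls
with eluent concentration) only; the published areas exist only graphically
and are not reproduced. The packaged fixture likewise attaches synthetic
area tables (labelled as such), so rendered trace heights are illustrative
while retention times, widths, resolutions and CF values are fully
model-based. Synthetic systems do not emulate detector noise, baseline
drift, peak-time measurement error, or inter-marker coefficient noise —
passing tests demonstrate correctness of the computation, not instrument
realism.

## Problem sizes in the test and acceptance runs

The acceptance computations use the study's own settings: 10 seeded GA
runs × 200 cycles × 30 offspring per cycle, each valuation integrating the
24 marker models at dt = 0.01 min over the 30-min horizon (batched across
the population in one vectorized march). The across-run resolution scatter
is computed from those 10 runs, a reduction of the study's 220-run
ensemble; with n = 10 a standard-deviation estimate itself carries ~25%
sampling error.

## Known limitations

* Single-competing-ion retention only; no temperature, flow-rate or
  multi-eluent dependence.
* No dwell-volume correction and no column re-equilibration modeling.
* The generalized logistic cannot represent tailing beyond a half-width
  ratio of ≈ 1.48 (see above).
* t_A is defined on the apex of the last peak; tailing-edge definitions
  would shift CF values slightly.
* The Doehlert initialization of the simplex is a regular-simplex subset
  with a configurable center; other construction choices change which local
  optimum a given (NF, Δc) run reaches.
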