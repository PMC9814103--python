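# Methods

## Design-space embedding

A condition is a point in a mixed space: continuous engineering
variables with inclusive bounds and a categorical micromixer choice.
For the surrogate, continuous values are min-max scaled to [0, 1] and
each k-way categorical becomes a k-dimensional one-hot block. Unit-cube
scaling was chosen because the variables span wildly different units
(0.01 M vs 60 °C); on a common scale a single lengthscale prior is
meaningful for every dimension.

Acquisition optimization runs over the relaxed box [0, 1]^D in which
one-hot blocks may be fractional. Relaxed vectors are made feasible by

1. clipping continuous coordinates to [0, 1] (never rejecting),
2. rounding each one-hot block to its nearest vertex — the largest
   component wins, ties broken toward the lowest choice index so the
   map is deterministic,
3. snapping continuous values to a per-parameter laboratory resolution
   grid (defaults: 0.1 equiv, 0.01 mol%, 5 °C, 0.001 M, 0.001 mL/min —
   the precision at which the recorded campaigns report conditions).

`decode(encode(c)) = c` holds exactly for every representable
condition; the tests enumerate small grids exhaustively.

## Flow arithmetic

The rig feeds two equal syringe streams into one mixer, so residence
time is t = V / (2 f) with V the mixer volume (Comet X 2.4 mL, β-type
2.7 mL, T-shaped 1.6 mL) and f the per-stream flow in mL/min. A few
printed residence values in the recorded campaigns (e.g. 5.5 min for
T-shaped at 0.15 mL/min, vs 1.6/0.3 = 5.33) appear to be rounded or to
include dead volume; the package treats V/(2f) as canonical and keeps
the printed value only as an informational column in the fixtures.

## Surrogate

A zero-mean GP on per-fit standardized yields with a Matérn-5/2 ARD
kernel over the full encoded vector, one-hot dimensions included as
ordinary coordinates — consistent with the relax-and-round treatment of
categoricals, and requiring no chemical descriptors. Constant targets
set the standardization scale to 1 instead of dividing by zero.

Hyperparameters maximize the log marginal likelihood with five
restarts of L-BFGS-B in log space (one default start, four seeded
log-uniform draws), making the fit deterministic given (data, seed).
Bounds: signal variance [1e-2, 1e2], noise variance [1e-6, 1]
(standardized units; the floor permits near-interpolation), and
lengthscales [0.1, 10] on the unit cube. The lengthscale floor of 10%
of a parameter's range encodes the assumption that yield surfaces do
not vary on scales finer than the lab can set a knob; with a smaller
floor the evidence can collapse into noise-free interpolation of
replicate-level noise, which destroys the explore/exploit balance of
any confidence-bound acquisition. Cholesky factorizations escalate
jitter 1e-10 → 1e-6 before reporting a numerical error; negative
posterior variances from round-off are clamped to zero.

## Acquisition and batches

The default acquisition is the optimistic confidence bound
α(x) = μ(x) + β·σ(x) on the yield scale with β = 2 held constant —
equivalently the lower confidence bound of the loss −yield, which is
the name used in the flow-screening context this package reproduces.
Stating the orientation explicitly avoids sign bugs: larger α is always
more promising. Expected improvement (with margin ξ) is available in
single and parallel forms.

Batches of q (default 3 — one experiment per available pump line) are
built sequentially. After each selection the model is conditioned on a
hallucinated observation equal to its own posterior mean there
("kriging believer"), which leaves the mean field unchanged and only
shrinks variance, then the acquisition is re-optimized. The inner
optimizer evaluates a seeded pool of 4096 uniform relaxed candidates,
locally refines the top 10 by bounded L-BFGS-B, snaps every candidate
to the lab grid, removes duplicates of the history and of the growing
batch, and — one deliberate refinement over argmax-then-snap —
re-evaluates the acquisition at the snapped points before choosing.
Scoring the condition actually proposed (rather than its relaxed
preimage) is what makes the selector exactly equal to exhaustive
sequential-hallucination enumeration on fully discrete spaces, which
the tests exploit as an oracle. Candidates are ordered
lexicographically before the argmax so ties are deterministic.

If every remaining grid point is a duplicate the proposal fails with an
exhaustion error rather than padding the batch.

## Synthetic benchmark

The closed loop cannot be validated on the recorded campaigns alone —
their suggested conditions depend on surrogate details that are not
recoverable — so optimizers are compared on a seeded synthetic yield
surface over the six-parameter screening space. Each mixer gets a
separable Gaussian bump in the unit-scaled continuous coordinates:
amplitude of the best mixer uniform in [80, 95] yield points with each
further mixer 10–20 points worse (the categorical choice must matter),
peak locations uniform in [0.15, 0.85], per-dimension widths uniform in
[0.5, 0.8]. The width range was calibrated so a typical random
condition yields 30–80% of its mixer's peak, matching the dynamic
range the recorded campaigns show for their six-point initial designs;
much narrower bumps would make the surface near-zero almost everywhere,
which is neither realistic for these couplings nor informative as a
benchmark. Observations add Gaussian noise (sd 2 yield points ≈
NMR-yield reproducibility) that is a pure function of (condition, seed,
call index), so runs are replayable. Landscape parameters are redrawn
per seed, so no test can overfit one surface.

What the generator does *not* emulate: asymmetric or multimodal
responses within a mixer, parameter interactions beyond the product
form, heteroscedastic noise, drift between days, and failed
experiments. Passing benchmarks therefore demonstrate correct and
competitive optimizer mechanics on smooth unimodal landscapes, not
performance guarantees on arbitrary chemistry.

Benchmark runs use budget 33 = 6 initial (Latin hypercube over the
continuous dims, mixers cycled for balanced coverage) + 9 rounds × 3,
over 20 seeds — the same shape as the recorded campaigns, extended to
a round count where optimizer differences are visible while keeping
the full suite to minutes on one CPU. Progress is measured on the
noiseless surface value of each evaluated condition (the observed
value would credit lucky noise), and `evals_to_threshold` is the first
evaluation reaching 95% of the landscape's true optimum, infinite when
never reached. Under these conditions the exploration constant β = 2
keeps proposing informative rather than incumbent-refining points, so
reaching the strict 95% band within 33 evaluations happens in a
minority of landscapes — but several times more often than random
search, which effectively never fine-tunes five continuous parameters
simultaneously; median final best-so-far also favors the BO loop.

## Campaign fixtures

The two recorded campaigns ship as checksummed CSVs (15 entries each):
six scattered initial conditions, then three rounds of three parallel
suggestions. Several suggested conditions lie outside the initially
announced screening ranges (3.5 equiv, 85 °C, 0.15 M, 0.014 mL/min,
0.25 mol%); the packaged `space_widened.yaml` therefore widens the
bounds to cover everything actually run, while `space_screening.yaml`
preserves the announced ranges. Replay statistics (per-round maxima,
running best) are computed from the fixtures at run time, never stored.

## Known limitations

* Box bounds only — no constraints, no conditional parameters.
* One categorical variable is assumed by the synthetic benchmark
  (the library itself supports any number).
* The GP is dense; fine for campaign-scale n (tens of points), not for
  thousands.
* β is constant; no schedule, no cost-aware or asynchronous batching.
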