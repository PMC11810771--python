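# Methods

## The selection problem

A bioimage method (convolution, interpolation, denoising) admits several
implementations that compute the same function by different strategies;
their relative speed depends on input shape, method parameters and host
hardware, and can invert across conditions. The engine's job is per-call
routing: given what has been observed so far, run the implementation with
the lowest expected cost, while remaining robust to transient slowdowns of
one backend.

## Run-time records and windowing

Every timed call appends one record — method, implementation, input
signature, wall-clock seconds, timestamp, device fingerprint — to a
JSON-lines file under `<store root>/<method>/<impl>.jsonl` (default
`~/.liquid_engine`, overridable per call or via
`LIQUID_ENGINE_STORE_ROOT`). Recency is insertion order, not timestamp, so
clock changes cannot reorder history. Retrieval returns at most the 50 most
recent times for an exact (signature, device) key; 3–49 records are used
as-is; fewer than 3 yields an explicit insufficient-history marker and the
caller falls back to the factory-default tables. Exactly 3 records counts
as sufficient: the fast/slow split needs at least two values, and the
fallback rule is phrased against histories smaller than three.

The device fingerprint is a SHA-256 digest (truncated to 64 bits) of
machine architecture, processor identifier, logical core count, total
memory and OS family. Records from other fingerprints are excluded from
retrieval rather than deleted, so switching back to a previous machine
revives its history.

## Split statistics and delay management

Per implementation, the retrieved times are sorted and split into a fastest
and a slowest half; with an odd count the median value joins the fast half,
biasing toward the optimistic baseline the delay test compares against.
Each half is summarized by its mean and *population* (divide-by-n) standard
deviation; the halves are small, so the estimator choice is a convention
fixed for reproducibility, not a statistical claim.

Delay entry, severity, expected cost and exit are the four closed forms:

* entry: `measured > FastAverage + 4·FastStdDev` (strict);
* severity: `DelayFactor = measured / FastAverage`;
* expected cost:
  `AdjustedRunTime = FastAverage·(1 − p_delay) + FastAverage·DelayFactor·p_delay`;
* exit: `measured < SlowAverage − SlowStdDev` **or**
  `measured < FastAverage + FastStdDev`.

The exit rule follows the "lower than" reading on both clauses; a
greater-than reading of the second clause would declare a delay over
*because* the run was slow, which contradicts the intended hysteresis.

`p_delay` is the probability the delay recurs on the next run. It is fit
by logistic regression (scikit-learn, L2-regularized, the run index as the
single covariate) on the last 50 observations of the per-implementation
delayed flag, evaluated at the next index. One-sided histories (all
delayed, none delayed) have no maximum-likelihood logistic fit, so they
return the Laplace-smoothed frequency `(k+1)/(n+2)`; results are clamped
to [0, 1]. Delay state is tracked per (method, implementation): a delay of
one backend must not contaminate the statistics of the others.

## Selection policy

With no delayed implementation the agent is deterministic: argmin of
FastAverage, ties broken by registration order. While any implementation
is delayed, each delayed one contributes its adjusted run time and each
normal one its FastAverage, and the agent samples from the inverse-square
distribution `P(k) ∝ 1/t_k²`. Inverse-square weighting concentrates mass
on the fastest implementation yet never zeroes a delayed one, so the agent
keeps probing whether the delay has lifted. Unavailable implementations
are excluded before any of this; registering a variant as unavailable
leaves it listed but never selectable.

All stochastic draws take an explicit integer seed. The engine derives a
per-call seed from (base seed, call counter) through `SeedSequence`, so a
run's decision sequence is reproducible from its configuration; wall-clock
measurements themselves remain machine-dependent, which is why the delay
experiment is evaluated over seeded replicates rather than exact traces.

## Fuzzy matching of input signatures

Each method maps a call to a fixed-order numeric signature (conv2d: H, W,
kernel size; upsampling: T, H, W, magnification; NLM: H, W, patch size,
patch distance, sigma, h). A query feature q is compared to a candidate
feature c by a triangular membership centered on c with half-width |c| —
membership 1 at equality, 0 at ±100 % relative difference — and a
candidate's score is the mean membership over features. The 100 % relative
half-width makes the score scale-free across features spanning orders of
magnitude (image sides of 10 to 20,000 next to sigma values below 1); mean
aggregation keeps a single very dissimilar feature from vetoing an
otherwise close match. Ties resolve to the earliest candidate in table
order. A zero-valued candidate feature matches only an exactly zero query.

## Kernels

All three methods clamp out-of-bounds reads to the nearest edge pixel, in
every implementation, so variants agree at borders too. Outputs are
float64 throughout.

**conv2d** computes the edge-clamped correlation
`out[i,j] = Σ_{u,v} ker[u,v]·img[clamp(i+u−K//2), clamp(j+v−K//2)]`.
Variants: numba scalar loops; row chunks dispatched to a thread pool, each
chunk evaluated by `scipy.signal.correlate2d` on a pre-padded slice; and a
tap-accumulation array expression over the padded image.

**catmull_rom_zoom** upsamples each frame independently by an integer
factor m with the cubic-convolution basis (a = −1/2):
`w(t) = 1.5|t|³ − 2.5|t|² + 1` for |t| ≤ 1,
`−0.5|t|³ + 2.5|t|² − 4|t| + 2` for 1 < |t| ≤ 2. Output pixel (i, j)
samples input position (i/m, j/m), pixel centers at integer coordinates,
0-based. Integer factors mean only m distinct sub-pixel phases exist, so
tap weights are precomputed per phase. The basis sums to 1 at every phase
(constant frames are reproduced exactly) and reproduces degree-1
polynomials in the interior; magnification 1 is the exact identity
(phase-0 weights are 0, 1, 0, 0). Non-integer factors are rejected — the
shipped use cases only need integer zooms, and restricting to them keeps
the phase table exact.

**nlm_denoise** replaces pixel i by the weighted average of all in-image
pixels j within Chebyshev distance `patch_distance`, with
`w(i,j) = exp(−max(d² − 2σ², 0)/h²)` and d² the *mean* squared difference
between the edge-clamped patches of side `patch_size` centered at i and j.
The sigma-compensated weight with mean (not sum) patch distance is the
variant consistent with exposing the (sigma, h) parameter pair in
intensity units. Weights are normalized to sum to 1 per pixel; the
self-weight is exp(0) = 1, not clamped — with the max(·, 0) flattening,
d²(i,i) = 0 already gives the maximal weight, so no special casing is
needed. Even patch sizes round up to the next odd integer so the patch has
a center pixel.

All NLM implementations use the offset decomposition: for a fixed
displacement o, d² for every pixel at once is a box sum of the squared
difference field `D_o(p) = (img[clamp(p)] − img[clamp(p+o)])²` evaluated on
a grid extended by the patch radius, which reduces the cost from
O(N·W·P) to O(N·W) for N pixels, window W and patch P. The extended-grid
construction makes the decomposition *exactly* equal to the per-pixel
clamped-patch definition, including at borders (clamping each patch
coordinate is not the same as clamping after shifting, so the field is
built from separately clamped source and target indices). Weight symmetry
w(i,j) = w(j,i) lets each half-plane offset serve both directions. The
`unthreaded` variant runs this decomposition as sequential numba loops —
a literal per-pixel quadruple loop would be numerically identical but
computationally infeasible on the default benchmark grid (a 500×500 image
with patch distance 100 implies ~10¹² patch operations); the quadruple
loop survives as the independent oracle in the test suite, on inputs of
16×16 and smaller. The `vectorized` variant evaluates each offset with
numpy plus `scipy.ndimage.uniform_filter` box sums; `threaded` distributes
offset chunks over a thread pool with per-thread accumulators.

Implementations differ in floating-point accumulation order, so
equivalence is tolerance-based (relative 1e−6 asserted; observed
deviations are at the 1e−13 level), not bit-exact.

## Benchmarking and factory defaults

`run_benchmark` crosses a signature grid with every available
implementation, generates the synthetic input per signature (uniform
noise; all-ones kernels), times `repeats` executions of the kernel call
only — input generation and store writes excluded — and records every run.
The first repeat is a warm-up: recorded like any other (so store
cardinality is predictable) but excluded from the reported median, which
absorbs JIT compilation and cache effects. Default repeats: 3.

The default grids scale down the full sweeps so a complete benchmark run
finishes in minutes: conv2d crosses image sides {100, 500, 1000} with
kernel sizes {1, 5, 9, 13, 17, 21}; Catmull–Rom upsamples stacks
{1×10×10, 10×10×10, 10×100×100, 10×300×300} at magnification 5; NLM
crosses sides {200, 500} with patch distances {10, 100} and patch sizes
{5, 10, 20} at sigma 1.0, h 0.1. The grid file format accepts arbitrary
user-defined grids for larger sweeps. The packaged factory-default tables
were produced by `build_factory_defaults` with 2 repeats per cell
(warm-up + 1 measured) — enough for the fast/slow split, while keeping the
heaviest NLM cells tractable; `liquidengine defaults rebuild` regenerates
them on any host, and a user table at `<store root>/defaults/<method>.json`
overrides the packaged one. Factory defaults are baselines for *relative*
comparison before local history exists; their absolute values reflect the
maintainer machine and are superseded after three local runs.

## The delay experiment

`run_delay_experiment` reproduces the sequential-run delay study at desk
scale: 60 sequential 9×9 convolutions of a 256×256 uniform-noise image,
with the preferred implementation's wall-clock inflated 8× during runs
15–29 (half-open window [15, 30)). Delay emulation is in-process: a busy
wait appended after the true computation, so outputs are unchanged and the
observable — inflated wall-clock for one implementation — is the same as
genuine hardware contention. Each experiment uses a fresh registry and
store; every implementation is first run 4 times pinned so local history
exists, then the initially fastest implementation (by FastAverage) becomes
the pinned policy's choice and, by default, the delay target. The adaptive
policy routes through the agent; the comparison metric is the mean run
time inside the delay window. At these problem sizes the three conv2d
variants have comparable baselines (milliseconds apart), which is the
regime where adaptive routing matters; the acceptance suite requires the
adaptive policy to win in at least 9 of 10 seeded replicates and the
delayed implementation's mean selection share to drop inside the window.

## What the synthetic data does and does not show

The generator produces uniform noise (benchmark and delay-experiment
inputs), Gaussian spots on background (visually meaningful denoising
demos) and exact linear ramps (interpolation tests). Uniform noise
exercises timing faithfully — kernel cost is data-independent for these
methods — but none of the kinds emulate microscopy statistics (Poisson
shot noise, structured background, camera offset), so passing tests
demonstrate correctness of the computation and the selection mechanics,
not denoising quality on real micrographs. Timing-dependent behavior
(which variant is fastest, how often spurious delays fire) is inherently
host-dependent; the acceptance checks are therefore properties (ordering,
shares, conformance) rather than absolute times.

## Numerical and design choices

* Strict inequality in delay entry; equality at the threshold is not a
  delay.
* Adjusted-time and probability arithmetic is plain scalar float64 in the
  stated order, making conformance checks exact.
* Insufficient-history is a falsy sentinel object, not an exception:
  empty history is an expected state, not an error.
* Delay bookkeeping engages only once an implementation's statistics come
  from same-device history. Factory defaults are baselines for relative
  comparison recorded on another machine under another load; judging a
  4-sigma delay gate against them would flag spurious, sometimes
  unclearable, delays during the bootstrap phase.
* Implementations with no history and no defaults (freshly registered
  user variants) receive a neutral prior equal to the mean baseline of the
  known ones, keeping them selectable so history can accrue.
* Decision traces are JSON log lines (method, signature, per-implementation
  statistics and sources, probabilities, chosen variant, decision latency),
  emitted through the `liquidengine.agent` logger for audit and testing.

## Known limitations

* Wall-clock timing at millisecond scale is noisy; with very tight
  FastStdDev an ordinary jitter can exceed the 4-sigma gate and trigger a
  brief stochastic episode. The exit rule recovers quickly, and the
  windowed statistics bound the impact.
* Selection is per-method and independent; multi-stage pipelines are
  optimized stage by stage, with no cross-stage co-optimization.
* The store is append-only JSON-lines without file locking; concurrent
  writers from multiple processes may interleave lines (each line is still
  atomic at typical sizes) but consistency is only guaranteed for a single
  writer.
* GPU backends are out of scope; implementation plurality is CPU-only.
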