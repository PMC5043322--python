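# Methods

## The model

`labsim` simulates a community of `N` research labs competing for
publication-based success. Each lab `i` carries three heritable
methodological traits:

- **power** `W_i ∈ [0, 1]` — the probability that the lab's full
  inferential chain yields a positive result when the investigated
  hypothesis is true;
- **effort** `e_i ∈ [1, 100]` — abstract methodological rigour, which
  suppresses false positives at the cost of slower output;
- **replication rate** `r_i ∈ [0, 1]` — the probability that an
  investigation targets a previously supported hypothesis instead of a
  novel one.

Three closed forms tie the traits together:

- investigation probability per time step:
  `h(e) = 1 − η·log10(e)` with `η = 0.2`, so `h(1) = 1` and `h(100) = 0.6`;
- false-positive rate: `α(W, e) = W / (1 + (1 − W)·e)`, a convex
  signal-detection trade-off — at `W = 0.8`, `α = 0.05` for `e = 75` and
  `α = 0.2` for `e = 15`;
- probability a novel investigation yields a (publishable) positive
  result: `Pr(+) = b·W + (1 − b)·α(W, e)` with base rate `b = 0.1` of true
  novel hypotheses. The expected false discovery rate among published novel
  positives is `(1 − b)·α / Pr(+)` (0.36 at baseline).

**Science stage.** Each step, labs act in a fresh random permutation. An
investigating lab replicates (with probability `r_i`, drawing uniformly
over *distinct* hypotheses that have at least one retained positive record)
or investigates a fresh novel hypothesis (true with probability `b`). The
experiment is a Bernoulli draw with success probability `W_i` (true
hypothesis) or `α(W_i, e_i)` (false). Positive novel results always
publish; negative novel results never do; replications publish with
probabilities `c_R+`/`c_R−` (both 1 by default). Publication pays the
author `V_N = 1` (novel) or `V_R± = 0.5` (replication); the hypothesis's
original author — if still active and distinct from the replicator — gains
`V_O+ = 0.1` on a successful replication or `V_O− = −100` on a failed one,
on every such event. Publications become visible (and replicable)
immediately, including to labs acting later in the same step.

**Evolution stage.** Once per step: a uniform sample of `d = 10` labs is
drawn and the oldest dies (ties uniform at random); from a fresh sample of
`d` survivors the highest-accumulated-pay-off lab reproduces (ties uniform
at random; if `d` exceeds the post-death population it is capped at that
size). The offspring starts at age 0 with pay-off 0 and inherits each trait
with independent mutation (probabilities `μ_w, μ_e, μ_r`; Gaussian
magnitudes `σ_w = 0.01, σ_e = 1, σ_r = 0.01`; values clamped to their
ranges). Finally the literature is truncated to its most recent
`10^6` records; hypotheses whose last retained positive record is dropped
stop being replicable.

## Backends and reproducibility

`run_simulation` exposes two backends with identical model semantics. The
`python` backend composes the documented per-operation functions and is the
readable reference; the `compiled` backend is a numba kernel over flat
arrays (population traits, a ring-buffer literature, an O(1)
insert/remove/sample index of replicable hypotheses) that runs a
million-step population in ~30 s, making the full published protocol
desk-feasible. The two backends consume their single seeded random streams
in different orders, so they agree statistically (tested against analytic
publication/replication rates and FDR) rather than draw-for-draw. Each
backend is individually deterministic: identical parameters and seed yield
byte-identical CSV output. Replicate runs use seeds `base_seed + k`.

Per-step FDR is recorded as missing (NaN), not zero, on steps without
published positives, and such values are excluded from replicate averages.
Metrics are sampled every `sample_interval = 2000` steps after the
evolution stage.

## Scenarios and problem sizes

Four presets reproduce the headline experiments: `power` (only `μ_w =
0.01`), `effort` (only `μ_e = 0.01`), `coevolution` (`r0 = 0.01`,
`μ_e = μ_r = 0.01`) and `enforced-replication` (`μ_e = 0.01`, `r` fixed at
a chosen level). The full protocol is 10^6 steps; trajectories reported by
the test suite use that horizon for the effort-collapse and
enforced-replication comparisons — the collapse of mean effort below half
its initial value occurs around 4.5–6×10^5 steps and so is invisible at
shorter horizons — with 6–8 replicates per condition (replicate counts are
sized so the whole suite runs on a single CPU in well under half an hour;
the power and coevolution direction checks use the 2×10^5-step scaled
preset where their effects are already decisive).

Observed behaviour: with power free to mutate, mean `W` and `α` reach 1
within ~5×10^4 steps. With effort free to mutate, mean effort declines to
its minimum with FDR rising above 0.8. Enforced replication at
`r ∈ {0, 0.25, 0.5}` delays the collapse monotonically (replicate-averaged
halving times ≈ 4.7×10^5, 5.9×10^5 and ≥6.8×10^5 steps) without preventing
it. In the coevolution scenario the mean replication rate rises rapidly
toward 1 while effort declines slowly — see "Known divergences" below.

## The two-type (static) model

The non-evolutionary comparison fixes `W = 0.8` and splits 100 labs
half/half between high effort (75) and low effort (15). Ten burn-in steps
with no replication seed the literature; 100 further steps follow in which
each investigation replicates with probability `r`. Pay-offs accumulate
over all 110 steps; nobody dies or mutates. With `r = 0` the type means
match the closed-form expectations `110·h(e)·Pr(+|e)` — ≈ 8.6 for high
effort and ≈ 21.9 for low effort — so low effort dominates. As `r` grows,
`V_O− = −100` penalties drag the low-effort mean below the high-effort
mean. Because the replicable pool in this small, short run holds only
~10^3 hypotheses while replication events arrive at ~35 per step at
`r = 0.5`, essentially every false positive is eventually caught and
nearly every lab is penalized; the top-pay-off lab is then usually a
rarely-penalized high-effort one. Sparse-penalty behaviour — where a few
low-effort labs escape punishment entirely and top the table — appears at
lower replication intensity (e.g. `r ≈ 0.05`). The panel presets
`{0, 0.25, 0.5}` are a documented assumption; the rate is fully
configurable.

## Power-review meta-analysis

`power_meta` treats one *review* as a (year, mean power) pair, pools
reviews with an **unweighted** mean (no weighting scheme is defined for
the source record), and fits power on year by OLS, reporting
`R² = 1 − SS_res/SS_tot` with the convention `R² = 0` for a zero-variance
response. `power_two_sample` uses the two-sided normal approximation
`Φ(d√(n/2) − z_{1−α/2}) + Φ(−d√(n/2) − z_{1−α/2})`, which a Monte-Carlo
t-test oracle confirms to within 0.01 at `d = 0.2, n = 50`; it exists for
fixture generation and sanity checks, not inference.

The synthetic review generator draws years uniformly over 1960–2011 and
powers as `clip(mean + slope·(year − midpoint) + N(0, sd), 0, 1)`. Its
defaults (44 reviews, mean 0.24, slope 0, sd 0.1) emulate the summary
statistics of the empirical record — a mean power of 0.24 for small
effects with no trend over five decades. The sd of 0.1 reflects the
visible between-review scatter; it is a modelling choice, not an estimate
from the original table, which is not shipped with this package. Synthetic
tables exercise the loading, validation and summary code paths; passing
those tests shows the statistics are computed correctly, not that any
particular empirical dataset has been reproduced.

## Numerical and design choices

- Trait mutation is applied then clamped; mutation draws happen only when
  the trait's mutation probability fires.
- An empty replicable pool converts a would-be replication into a novel
  investigation, so `h(e)` alone governs productivity.
- A lab may replicate its own hypothesis; originator pay-offs apply only
  when replicator and originator differ, and only to the hypothesis's
  novel author.
- Offspring inherit traits only — no pay-off, age or publication history.
- Config files are flat YAML mappings of the parameter names; unknown keys
  are rejected, omitted keys take defaults, and round-trips are lossless.
- The `d = 0` effect-size case of `power_two_sample` returns exactly α.

## Known divergences from the published account

Two published quantitative claims do not emerge from this implementation
of the stated mechanics, and the corresponding acceptance checks are left
failing rather than adjusted:

1. **Evolved replication rate in the coevolution scenario.** A replication
   investigation pays 0.5 with guaranteed publication versus an expected
   0.125 for novel work at initial conditions — a ~4× per-investigation
   advantage — while the −100 deterrent almost never binds (targets are
   drawn uniformly from ~10^5 replicable hypotheses, so a *living*
   originator is rarely struck). Selection therefore drives the mean
   replication rate toward 1 long before effort collapses, rather than to
   the published ≈ 0.08. The published figure plausibly depends on
   implementation details not recoverable from the text.
2. **Top-pay-off lab type in the static model at `r = 0.5`.** As described
   above, penalty saturation at this replication intensity makes the top
   lab high-effort in ~96% of runs; the published "the very highest
   performers exert low effort" behaviour appears when penalties are
   sparse (lower `r`). The `r` values behind the published pay-off
   histograms are not stated.

## Limitations

Hypotheses are strictly true or false (no effect sizes); there are no
journal tiers, no collaboration, no variable lifespans, and no parallel
execution contract. The synthetic review generator emulates summary
structure, not the provenance or heteroscedasticity of real review data.
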