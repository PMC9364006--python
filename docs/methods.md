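# Methods

## The design problem

A study area is partitioned into `N` quadrats of unit area. Per-quadrat
abundances `X_1, ..., X_N` are independent and identically distributed, either
Poisson(λ) or Negative Binomial NB(r, λ) in the mean parameterization
(`p = λ/(r+λ)`; variance `λ(1+λ/r)`). The species is *present* when the area
total `Y = Σ X_i` is positive. A survey samples `n` quadrats at random and
declares the species absent if no individual is detected in any of them. The
design question is the minimal `n` with

    P(zero detections in the n samples | Y > 0) <= beta.

Both families are closed under summation (`Σ_{i<=n} X_i` is Poisson(λn) or
NB(rn, p)), so the conditional probability has a closed form. For the Poisson
model with perfect detection,

    P = (e^{-λn} - e^{-λN}) / (1 - e^{-λN}),

and inverting `P <= β` gives `n = ⌈-log(β + (1-β)e^{-λN}) / λ⌉`, which always
lies in `[1, N]`. Its `N → ∞` limit is the classical `⌈-log(β)/λ⌉`; the
difference between the two (the cost of ignoring a known area size) is at
most `⌈log(1 + e^{-λN}(1-β)/β) / λ⌉` and equals that bound minus one once `N`
is large enough. The NB analogue replaces `e^{-λm}` by
`(1+λ/r)^{-rm}`; because `(1+λ/r)^{-r} > e^{-λ}` (excess zero mass), the NB
design never needs fewer samples than the Poisson design at equal mean, and
all NB formulas converge to their Poisson counterparts as `r → ∞`.

## Imperfect detectability

Each individual present in a sampled quadrat is detected independently with
probability `1 - δ` (false negatives only; false positives are assumed
impossible). Binomial thinning maps the detected count in `n` quadrats to
Poisson(λ(1-δ)n) or NB(rn, mean λ(1-δ)n), so the detection term of the
probability substitutes `λ(1-δ)` for `λ` while the presence-conditioning
terms `P(Y > 0)` — a property of the *true* abundance — keep `λ`. For the
Poisson model this yields

    P = (e^{-λ(1-δ)n} - e^{-λN}) / (1 - e^{-λN}),
    n = ⌈-log(β + (1-β)e^{-λN}) / (λ(1-δ))⌉.

For the Negative Binomial finite-area case two variants are shipped
(`--nb-delta-variant`):

* **printed** (default): `λ(1-δ)` substituted in *every* term, including the
  `(1+λ(1-δ)/r)^{-rN}` presence terms — the formula as published;
* **consistent**: the thinned mean only in the detection term, `λ` retained in
  the presence terms, mirroring the Poisson treatment.

The two differ only when the area is small enough for `(1+λ/r)^{-rN}` to
matter; only the consistent variant recovers the Poisson δ-formula in the
`r → ∞` limit, and it is the analytic counterpart of the simulator (which
thins true counts). Both reduce to the δ = 0 formula exactly. `δ = 1` is
rejected: the requirement diverges.

The guarantee `n <= N` is proved only for δ = 0. With detection error the
requirement can exceed the area; the result is then returned **uncapped**
with `feasible=False` and the achieved probability reported at `n = N`
(capping silently would quietly void the β guarantee). The CLI signals this
with exit code 3.

## Parameter estimation

With δ treated as known (it is never estimated here):

* **Poisson**, from a detection summary (`n0` quadrats, `w` with at least one
  detection): `λ̂ = -log(1 - w/n0) / (1-δ)`, inverting the per-quadrat
  detection probability `1 - e^{-λ(1-δ)}`. `w = n0` makes the estimate
  unbounded (error); `w = 0` returns 0 with a warning.
* **Negative Binomial**, from per-quadrat detected counts: the natural
  (biased) moment estimators `λ̂ = x̄/(1-δ)`, `r̂ = x̄²/(s² - x̄)` with `s²`
  the uncorrected (1/n0-divisor) sample variance. Thinning preserves `r` and
  scales the mean, so only `λ̂` carries the `1/(1-δ)` correction. `s² <= x̄`
  (no observed overdispersion) is an error directing the user to the Poisson
  model; no bias correction is applied.

`r` is accepted as any positive real: the formulas are well defined for real
`r` and the moment estimator returns one.

## Monte Carlo validation

Each replicate draws the abundance over the whole area, conditions on
presence by rejection (replicates with `Y = 0` are discarded, matching the
conditional probability being estimated), applies per-individual detection
error, and records whether the `n` sampled quadrats produced zero detections.
`p_hat = failures/accepted` with binomial standard error
`sqrt(p_hat(1-p_hat)/accepted)`.

The default **aggregated** mode draws only the sufficient totals — sampled
total, unsampled remainder — using the additivity of both families, and thins
the sampled total with one Binomial draw (per-individual misses commute with
summation for the "nothing detected" event). This makes `K = 10⁷` replicates
at `N = 3000` take about a second instead of ~3×10¹⁰ individual draws. The
**per_quadrat** mode draws all `N` per-quadrat counts and thins each sampled
quadrat separately — the simulation taken literally — and is kept to certify
the aggregated shortcut (they agree within Monte Carlo error; property-tested
at small `N`). A single named `numpy` generator is seeded explicitly
(CLI default seed 20220046).

## Synthetic counts

`generate_counts` emulates a pilot survey: true per-quadrat counts from
Poisson(λ) or NB(r, λ), each individual retained with probability `1-δ`. It
reproduces exactly the distributional assumptions of the design model —
spatial independence, homogeneous density, individual-level detection error.
Real survey data violate these in known ways (spatial clustering beyond what
NB overdispersion captures, density gradients, detection error correlated
within visits or observers), so estimator-recovery tests passing on this
generator demonstrate correctness of the formulas under their own
assumptions, not robustness to model misspecification.

Default test/validation scales: estimator recovery uses `n0 = 10⁵` quadrats
(where the moment estimators' sampling error is comfortably inside ±2% for
λ, ±10% for (r, λ)); simulator checks use `K = 10⁵–10⁶` replicates with a
4-standard-error tolerance (per-comparison false-alarm rate ≈ 6×10⁻⁵); the
reference validation of the headline design uses `K = 10⁷`, the scale at
which the published probabilities were computed. The `tables` subcommand
defaults its stochastic columns to `K = 10⁶` with `--full` for `10⁷`.

## Numerical choices

* NB powers `(1+λ/r)^{-rm}` are computed as `exp(-rm·log1p(λ/r))`, keeping
  the `r → ∞` and large-`N` regimes accurate (verified by integer agreement
  with the Poisson formulas at `r = 10⁸`).
* Ceilings are verified, not trusted: the real-valued bound is computed in
  double precision, then the candidate `⌈x⌉` (with a 10⁻⁹ guard against FP
  noise at integer boundaries) is checked against the defining inequality and
  adjusted by ±1 if needed. The published tables are exact integers;
  floating-point rounding must not flip them.
* An unbounded area is a first-class sentinel (`INFINITE`), dispatching to
  the limit formulas rather than emulating `N = huge` (avoids `e^{-λN}`
  underflow ambiguity).
* Probabilities are clamped at 0 from below (the `n = N`, δ = 0 case is an
  exact cancellation); outputs print at 8 decimal places.

## Known limitations

* Sampling is assumed unbiased (quadrats chosen at random); spatially biased
  or adaptive designs need different models.
* False positives are assumed impossible (`f_p = 0` throughout).
* δ must be supplied by the user (from calibration studies or expert
  judgment); no within-package way to estimate it.
* No interval estimates for λ̂ or r̂, and no maximum-likelihood NB fitting —
  the moment estimators are the supported path.
* No explicit zero-inflated mixture models; the NB's own zero inflation is
  the supported mechanism.
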