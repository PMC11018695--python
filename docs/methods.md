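# Methods

## Model and assumptions

Candidates form K disjoint sets Π_1 … Π_K with pool proportions π_k
(Σπ_k = 1).  Within set k the selection criterion (SC) is i.i.d.
N(μ_k, σ_k²) and the true genetic value (TGV) regresses linearly on the SC
with slope b_k; the joint distribution is taken bivariate normal.  The two
supported criterion types pin down (σ_k, b_k) from the genetic standard
deviation σ_u and a quality parameter:

| criterion | quality parameter | SC sd σ | slope b |
|-----------|-------------------|---------|---------|
| BLUP      | accuracy ρ ∈ (0,1] | ρ·σ_u  | 1       |
| BLUE      | heritability h² ∈ (0,1] | σ_u/h | h² |

BLUPs are shrunken toward the mean (σ < σ_u) but unbiased as predictors, so
TGV-on-BLUP slope is 1; BLUEs are noisy measurements (σ > σ_u) and TGVs
regress on them with slope h².  A BLUE set with h² = 1 coincides with a BLUP
set with ρ = 1.

Truncation at threshold t_k selects the upper tail
α_k = 1 − Φ((t_k − μ_k)/σ_k) of set k.  The pool-level closed forms are

* α_Tot = Σ α_k π_k,
* γ_k = α_k π_k / α_Tot (post-selection composition; Σγ_k = 1),
* ΔG_k = b_k σ_k i(α_k) with i(α) = φ(Φ⁻¹(1−α))/α,
* ΔG_Tot = Σ ΔG_k γ_k + Σ μ_k (γ_k − π_k).

**Baseline convention.**  ΔG_Tot is the expected mean TGV of the selected
union minus the mean TGV of the *unselected* union, Σ π_k μ_k.  The
mean-shift terms μ_k(γ_k − π_k) account for composition changes; they vanish
when all sets share one mean, and they can dominate (even making ΔG_Tot
negative) when stringency is allocated against the better set.

For all-BLUP pools at a common threshold t*, substitution of b = 1 and
γ_k = α_k π_k/α_T gives the equivalent direct form

ΔG_Tot = (1/α_T)[ Σ σ_k φ(z_k) π_k + Σ μ_k π_k (α(z_k) − α_T) ],
z_k = (t* − μ_k)/σ_k,

implemented as `blup_total_response_closed_form` and cross-checked against
the general expression to 1e−10.  The analogous direct BLUE form carries the
same 1/α_Tot prefactor on its density terms; the package keeps the general
composition-weighted expression as the single source of truth and verifies
the direct form in the test suite.

## Threshold optimization

Budget: α_Tot(t_1, …, t_K) = α_T fixed.  Because each α_k is strictly
decreasing in t_k, α_Tot is strictly decreasing along any monotone threshold
path, which makes both solvers one-dimensional bracketed root problems
(Brent's method, xtol 1e−14):

* **Identical threshold** — root of α_Tot(t, …, t) = α_T.
* **Optimal thresholds** — the Lagrange stationarity condition for
  maximizing ΔG_Tot under the budget requires b_k(t_k − μ_k) + μ_k to take a
  common value c across sets; substituting t_k(c) = μ_k + (c − μ_k)/b_k
  reduces the problem to a root in c.  For b_k ≡ 1 (BLUPs) the manifold
  collapses to t_1 = … = t_K: a uniform threshold is provably optimal for
  BLUP selection, which the suite verifies over randomized scenario
  batteries (threshold spread ≤ 1e−7, |Ψ_Tot| < 1e−6).

Thresholds are bracketed within [min_k(μ_k − 10σ_k), max_k(μ_k + 10σ_k)]
(tail mass outside is < 1e−23, far below any meaningful budget); the bracket
expands geometrically a few times before the solver reports failure.  For
finite thresholds every per-set α is strictly interior, so no clamping to
α ∈ {0, 1} is ever required; tail proportions that underflow to 0 (or
saturate at 1 in double precision) contribute zero intensity, the exact
limit.

Ψ_Tot = 100·(ΔG_Tot(optimal) − ΔG_Tot(identical))/ΔG_Tot(identical)
requires a positive denominator; a non-positive identical-threshold response
(possible when a wide, inferior set swamps the selection) raises
`UndefinedRatioError` rather than returning a sign-flipped ratio.  This
error contract is the package's choice for a case the underlying theory
leaves open.

`direct_constrained_maximize` is an independent check: it eliminates the
last set's proportion through the budget and maximizes ΔG_Tot numerically
(bounded scalar search for K = 2, Nelder-Mead from the identical-threshold
start for K ≥ 3).  Lagrange and direct solutions agree to 1e−6 in ΔG_Tot
across randomized batteries; if they ever disagreed beyond that, the better
one is returned with a logged warning.

## Hybrid GCA selection

Pools Π_1 × Π_2 produce a complete factorial of hybrids; each pool's GCA
criterion is N(0, σ_k²) with slope b_k.  Retaining proportions (α_1, α_2) of
lines keeps α_1·α_2 of the hybrids, so a hybrid budget α_H constrains the
product.  The response of the selected factorial over the unselected one is
ΔG_Hyb = b_1σ_1 i(α_1) + b_2σ_2 i(α_2); no parental-control or cycle-length
factors are applied.

The optimizer searches α_1 ∈ [α_H(1+ε), 1−ε] (ε = 1e−12) with
α_2 = α_H/α_1, which enforces the budget exactly and makes the problem
one-dimensional.  The stationarity function
b_2 t_2 − b_1 t_1 + ΔG_1 − ΔG_2 runs from −∞ to +∞ along this manifold, so
Brent's method on it is the primary route; if no sign change is bracketed
the code falls back to direct bounded maximization and flags near-edge
optima as `boundary`.  The equal split α_1 = α_2 = √α_H is the baseline for
Ψ_Hyb.  Stringent selection concentrates in the pool with larger σ·b; the
split is exactly even iff σ_1 b_1 = σ_2 b_2.

At pool SD ratio σ_2:σ_1 = 0.5 with b = 1, the computed Ψ_Hyb is 9.4%, 7.2%,
and 6.4% for α_H = 0.25, 0.01, and 1e−4 — roughly 6% only under stringent
selection, with a mild-selection value noticeably higher.  (These are the
values the acceptance script computes; both the stationarity root and the
direct maximizer produce them, agreeing to better than 1e−7.)

## Numerical choices

* All tail probabilities go through survival functions (`norm.sf`,
  `norm.isf`), never 1 − cdf, preserving relative precision in the far tail.
* i(α) = φ(Φ⁻¹(1−α))/α is evaluated directly: with α as the *input* there is
  no 0/0 cancellation, and the ratio is accurate down to α ≈ 1e−300.  Only
  where φ underflows to subnormals (standardized threshold > 38, α below
  ~3e−316) is the Mills-ratio asymptotic i ≈ x + 1/x substituted.
* Root solves use Brent's method with xtol 1e−14; solutions record the
  residual budget violation and a convergence flag (required ≤ 1e−9).
* Validation rejects π_k ∈ {0, 1} for K ≥ 2, σ_u ≤ 0, and accuracy outside
  (0, 1]: each makes a formula degenerate.  A single-set scenario (π = 1) is
  allowed and reduces every formula to the classical breeder's equation.

## Monte-Carlo oracle

`simulate_candidates` draws sc ~ N(μ_k, σ_k²) and then
tgv | sc ~ N(μ_k + b_k(sc − μ_k), v_k) with residual variance
v_k = σ_u²(1 − ρ²) (BLUP) or σ_u²(1 − h²) (BLUE).  The conditional-normal
factorization was chosen over joint draws because it makes the two
theory-relevant quantities (SC variance, TGV-on-SC slope) and the residual
variances explicit and directly testable.  Per-set substreams are spawned
from one master `SeedSequence`, so runs are bit-reproducible and the draws
of a set do not depend on how many sets follow it.

Agreement tolerances for empirical vs. analytic quantities are expressed in
Monte-Carlo standard errors (4 SE) rather than fixed epsilons, giving a
principled stochastic acceptance at any sample size.  The routine test suite
uses 2×10⁵–4×10⁵ draws per set for moment and agreement checks and 10⁶ per
set for the full-scale agreement test — sizes at which 4 SE is a fraction of
a percent of the checked quantities while the whole suite runs in seconds.

What the simulation emulates — and what it does not: candidates are i.i.d.
within sets with exactly normal criteria and linear TGV-on-SC regressions.
Real programs have related candidates, unbalanced data, non-normal traits,
and estimated (not known) population parameters, so passing tests validate
the closed forms under their own assumptions, not robustness to violations
of those assumptions.  Finite candidate lists (selecting exactly n-best
rather than thresholding) coincide with truncation selection only
asymptotically; no finite-sample correction is implemented.

## Parameter-grid scans

The `scan` machinery reproduces the method's behavior maps as tidy CSV
tables: `gamma_ratio` (composition shift γ_1*/π_1 for BLUP pools over
(μ_2, ρ_2), set 1 fixed at μ_1 = 0, σ_u = 1, ρ_1 = 0.5), `psi_tot` (Ψ_Tot
for BLUE pools over (μ_2, h_2)), and `hybrid` (Ψ_Hyb over the pool SD
ratio).  The first set's heritability in `psi_tot` is an explicit parameter
`h1_sq` (default 0.50) rather than a hard-wired constant.  Scans are pure
functions of their spec; re-running one yields byte-identical CSV.  Contour
rendering is optional (`--plot`), since the scan's purpose is numeric.

## Known limitations

* Two criterion families only (BLUE/BLUP); no non-normal criteria, no
  covariances between sets, no multi-trait indices.
* Population parameters are taken as known; no estimation from data and no
  propagation of their uncertainty into thresholds.
* Hybrid selection covers the complete factorial on parental GCA only —
  no partial-factorial selection on GCA sums, no SCA effects.
* Single-cycle response; no recurrent selection, no drift or inbreeding
  accounting, no optimum-contribution constraints on relatedness.
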