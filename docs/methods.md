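# Methods

## Models

All models are dichotomous multidimensional Rasch models. Person `p` answers
item `i` correctly with probability

    P(x_pi = 1 | theta_p) = logistic( b_i' theta_p - d_i ),

where `theta_p` is a D-dimensional latent vector, `b_i` is row `i` of the
scoring matrix `B` (the fixed 0/1 — or 0/1/−1 for the subdimension family —
loading pattern), and the item difficulties compose as `d = A beta` through a
design matrix `A`. Latent vectors follow a multivariate normal with mean zero
and covariance `Sigma`. The families differ only in `B` and in which entries
of `Sigma` are free:

| family | covariance pattern | scoring matrix |
|--------|--------------------|----------------|
| CORB | all entries free | loading pattern |
| RTM  | diagonal | loading pattern |
| ETM  | general–specific covariances free, specific block diagonal | loading pattern |
| SORB | general orthogonal to specifics, specific block free | loading pattern |
| GSM  | general orthogonal to *retained* specifics, retained block free | zero-sum reduced (D = S) |
| SRM  | GSM with equal retained specific variances | zero-sum reduced |

The subdimension family (GSM/SRM) re-expresses one specific factor as the
negative sum of the others; its retained-factor column `j` of `B` equals
`loads[:, j] − loads[:, excluded]`, which covers clear structures, construct
items (G-structures) and shared items alike. We use the simplified
parameterization in which specific-variance heterogeneity is absorbed into
`Sigma` rather than carried by explicit per-factor scale parameters; the SRM
is obtained by tying the retained specific variances through the pattern's
tie-group mechanism. With two specific factors the zero-sum constraint makes
the implied specific-factor correlation exactly −1, so the family is reported
but flagged as degenerate there.

## Identification

A completely oblique structure is analytically identified iff a D-set item
partition exists whose set-sum matrix `C` (row i = column sums of `B` over
set i) is nonsingular; the reduced design matrix `A'` then drops one item
parameter per set, re-expressed as the negative sum of its set-mates
(anchored at zero for singleton sets). Because each row of `C` lies in the
row space of `B`, such a partition exists iff `B` has full column rank, and
singleton sets suffice as witnesses — the `rank` method exploits this; the
`brute_force` method searches all singleton-set partitions exhaustively and
serves as an oracle in the tests. `C` is integer-valued for 0/1/−1 scoring,
so its determinant is computed exactly (fraction-free Bareiss elimination);
the 1e-9 tolerance only guards float inputs. Of the necessary conditions
stated for the general procedure we implement the two that are forced by
linear algebra — `n_items >= D` and `rank(B) = D`; the remaining published
inequalities could not be transcribed from our source material, but the rank
reading reproduces every verdict we can check (clear structures fail; G- and
S-structures pass; all subdimension reparameterizations pass with equal
absolute determinants under a common partition).

## Estimation

`fit()` maximizes the marginal likelihood by EM:

* **E-step.** Posterior weights of each person over quadrature nodes
  `theta_q = mu + L z_q`, with `L` the Cholesky factor of the current
  `Sigma` and `z_q` fixed standard-normal base nodes.
* **M-step.** Newton ascent on the expected complete-data log-likelihood for
  the reduced item parameters (the Hessian is diagonal in difficulty space,
  so the reduced-space Newton system is tiny), then the latent means (their
  MLE is the average posterior mean) and the pattern-constrained covariance.

**Latent means.** When `A` is reduced, the latent means are estimated freely
and folded back into the reported difficulties (`beta_hat = A beta − B mu`),
so everything is reported on the conventional zero-latent-mean scale. This
is the likelihood-preserving shift that the reduced design matrix exists to
pin down; it makes the fitted deviance invariant to the choice of witness
partition (checked to 1e-3 in the tests) and the reported difficulties
directly comparable to generating values. When `A` is the full identity
(the orthogonal RTM on clear structures, where no reduced design exists),
means are fixed at zero instead; the two parameterizations have the same
item-side dimension. The free-parameter count used in AIC/BIC is
`columns(A) + free covariance entries`; the profiled means are not counted,
and since every family compared on one structure shares the same design
matrix convention, information-criterion orderings and likelihood-ratio
degrees of freedom are unaffected.

**Constrained covariance update.** A fully free pattern takes the average
posterior second-moment matrix itself; a diagonal pattern takes its
diagonal. Mixed patterns (ETM/SORB/GSM/SRM) are solved by Fisher scoring on
the normal log-likelihood over the free entries with zeros held, started
from the pattern-projected moment matrix (off-diagonals shrunk toward the
diagonal until positive definite) and eigenvalue-floored at 1e-6. Flooring
is recorded as a warning on the fit.

**Acceleration.** Plain EM is provably slow here: the completely oblique
covariance entries carry little information per item (especially with a
single construct item), the likelihood is flat, and a fixed-point iteration
creeps — we measured plain EM triggering a 1e-5 deviance-change stop while
still 0.15 deviance units short of the optimum the accelerated fit reaches.
We therefore interleave plain EM steps with SQUAREM extrapolations of the
EM map. Every extrapolated point is re-evaluated; if it does not improve
the quadrature log-likelihood it is discarded in favor of the plain step,
so accepted iterates remain monotone up to integration noise.
`accelerate=False` recovers the pure alternation. Convergence requires a
log-likelihood change below `tol` (default 1e-5) *and* a maximum parameter
change below `param_tol` (default 1e-4), within `max_iter` (default 500)
EM-map evaluations.

**Flat ridges and the plateau stop.** The completely oblique covariance is
weakly informed when a structure has few construct or shared items: the
likelihood forms a long, nearly flat ridge, along which the
quadrature-approximate EM map can creep indefinitely (and, at QMC
resolution, even drift slightly downhill, since the map's fixed point and
the quadrature likelihood's maximum coincide only up to integration
error). The fitter therefore tracks the best iterate seen and stops —
reporting convergence with a "log-likelihood plateau" warning — once 30
consecutive evaluations fail to improve the log-likelihood by `tol`; the
best point, not the last, is returned. On flat likelihoods a warm start
from a nested model's solution parks the general model far along the
ridge, which distorts covariance recovery while leaving the deviance
essentially unchanged; the simulation harness therefore fits every family
from its own default start and falls back to a warm refit only if the
fitted deviances invert the nesting hierarchy.

**Numerical integration.** Product Gauss–Hermite with 15 nodes per
dimension for D ≤ 3; for D ≥ 4 the product rule explodes combinatorially,
so we switch to 2048 scrambled Sobol points mapped through the normal
quantile function (seeded, hence bit-for-bit reproducible). The base nodes
are fixed across EM iterations and recentred through `mu + L z`. Quadrature
noise of the QMC rule is visible as occasional ~1e-5-scale wiggles in the
likelihood history; the Gauss–Hermite paths are monotone to 1e-6.

**Starting values.** Difficulties from the logit of observed item means
(solved through `[A, −B]` by least squares so the start respects the
reduced parameterization), covariance at the pattern-projected identity.
Warm starts are supported; `fit_hierarchy()` fits RTM → ETM → CORB in
sequence, each started from the previous solution, which both speeds the
oblique fits and keeps fitted deviances consistent with the nesting
hierarchy.

**Missing data.** Missing responses are skipped in the per-person product
(missing at random), the standard marginal-ML treatment.

## Person scores

EAP scores are posterior means under the fitted parameters, reported on the
zero-latent-mean scale, with posterior SDs from the same pass. Because the
posterior uses the full fitted covariance, correlated dimensions reinforce
one another. EAP reliability per dimension is
`1 − mean(posterior variance)/fitted variance`, clipped to [0, 1]; a zero
fitted variance yields reliability 0 with a warning.

## Simulation study

The generator draws latent covariances with variances uniform on
[0.3, 4] logits and correlation matrices uniform over the space of valid
correlation matrices (vine construction with Beta-distributed partial
correlations), item difficulties equally spaced on [−2, 2] across the whole
test (a per-factor grid is available as a switch), and Bernoulli responses
through the logistic model; sample size defaults to 2000 persons with items
assigned to specific factors in alternation (block assignment available).
These defaults are the study conditions; scaled-down runs change only the
replication count.

Recovery metrics: the correlation-matrix RMSE is the root mean squared
Frobenius distance between estimated and true *correlation* matrices across
replications (the correlation scale makes the measure robust to the widely
varying variance draws); variance bias is the per-dimension mean and SD of
estimated minus true variances; EAP–truth Pearson correlations and EAP
reliabilities are averaged per dimension. The subdimension family is
calibrated once per exclusion choice, results averaged entry-wise and its
full covariance assembled by `gsm_gather` (duplicated entries averaged,
with diagnostics for duplicate disagreement and for consistency with the
zero-sum-implied completion). Replications whose fit did not converge are
excluded from that model's metric averages and surfaced as a convergence
rate; convergence-failure *rates* depend on estimator internals that differ
across software, so only their qualitative pattern is meaningful. Because
the gathered subdimension covariance structurally zeroes the
general–specific covariances, its correlation RMSE against an oblique truth
is expected to exceed the completely oblique model's — that ordering, with
the information-criterion ordering, is what the test suite asserts.

The bundled reading-assessment fixture is synthetic: it emulates a
35-item G-structure (specific factors of 9, 9 and 3 items plus 14
construct items) with 1000 respondents drawn from a plausible oblique
truth that includes one negative general–specific correlation of the
explaining-away kind. It reproduces the *design* of such an assessment,
not any empirical response distribution: real data exhibit
guttmanized response profiles, discrimination heterogeneity and
item-level misfit that the Rasch generator does not create, so passing
tests on the fixture demonstrate correctness of the machinery, not fit of
the model to any particular real test.

## Problem sizes and numerical choices

The test suite runs the recovery study at 10 replications of the baseline
condition (3 specifics × 5 items + 1 construct item, N = 2000) — large
enough for the orderings under test to be stable across seeds, small enough
to keep the suite responsive. Tolerances: deviance comparisons to 1e-3
(integration-noise floor of the QMC rule at N = 2000); the
constrained-update oracle comparison to 1e-6; the quadrature-vs-grid oracle
to 1e-4 with a 201×201 grid on [−6, 6]². Determinant tolerance 1e-9 (exact
integer arithmetic makes it moot on integer scoring). Eigenvalue floor 1e-6
for covariance updates. Degenerate inputs: items answered identically by
everyone get difficulty starts clipped at logit(0.02/0.98); persons or
items with no observed responses are rejected at validation.

## Known limitations

* Dichotomous items only; no polytomous scoring matrices.
* Rasch discrimination (all loadings fixed at unity); no 2PL counterparts.
* Analytical identification only — empirically identified
  covariance-constrained variants are out of scope.
* No item-fit statistics or standard errors by default (observed-information
  SEs would require an extra differentiation pass; none of the reported
  quantities need them).
* Convergence-failure rates are estimator-specific and not comparable across
  software beyond their qualitative trend.
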