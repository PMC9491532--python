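# Methods

## Data model

The synthetic generator (`acoscale.simulate`) produces ordinal item
responses from a latent-response model. Each item *i* has a continuous
latent variable with unit total variance; the observed category (0–4) is
the number of the item's four thresholds lying below the latent value.
Two latent structures are supported:

* **bifactor** — latent_i = g_i·G + s_i·S_d(i) + √(1−g_i²−s_i²)·e_i with
  the general factor G and four domain-specific factors mutually
  orthogonal;
* **hierarchical** — first-order domain factors F_d = γ_d·G + √(1−γ_d²)·u_d
  and latent_i = λ_i·F_d(i) + √(1−λ_i²)·e_i, so all cross-domain
  covariance flows through the second-order severity factor.

For patients the general factor G has mean δ instead of 0 (group shift in
standardized units). The implied latent correlation matrix has closed
form (`implied_latent_correlation`): λ_iλ_j within a domain and
λ_iγ_dγ_eλ_j across domains for the hierarchy; g_ig_j + [same domain]
s_is_j for the bifactor.

**Default study conditions.** 97 items split 25/24/24/24 over the four
domains (the true composition of the real instrument is unpublished;
the split is configurable), two subscales per domain; 337 controls and
96 patients; δ = 2.1, the long-form patient–control effect size the
instrument family reports. First-order/general loadings are drawn
U(0.5, 0.8), bifactor specifics U(0.2, 0.5), higher-order paths
U(0.5, 0.8). Thresholds sit at the standard-normal quantiles of
cumulative probabilities (.50, .75, .90, .97) plus U(−0.1, 0.1) jitter —
right-skewed pathology items: most healthy controls endorse the lowest
categories. Missing data are off by default; an MCAR mask with a stated
rate is available. All randomness flows through one seeded
`numpy.random.Generator`; the pipeline fans a single top-level seed into
per-stage substreams via `SeedSequence` so stages can be re-run in
isolation.

**What the generator does *not* emulate:** item-specific content
(cross-loadings, local dependence between paraphrased items), differential
item functioning between groups, non-normal latent traits, and
informative missingness. Passing tests therefore demonstrate correctness
of the estimators and the optimizer under the assumed model, not
robustness to real-data violations of it.

## Polychoric correlations

Two-step estimation, the standard practice: thresholds from the marginal
cumulative proportions (Φ⁻¹), then per pair the maximum-likelihood
correlation of a latent bivariate normal given the fixed thresholds,
found by bounded scalar minimization of the multinomial deviance over
ρ ∈ (−0.9995, 0.9995) (tolerance 1e-7). Cell probabilities come from a
vectorized port of the Drezner–Wesolowsky/Genz bivariate-normal CDF
(20-node Gauss–Legendre, separate high-|ρ| branch), accurate to ~1e-14
against `scipy.stats.multivariate_normal` and fast enough for the ~10⁵
likelihood evaluations a 97-item matrix needs. Degenerate items (all
mass in one category) are flagged and excluded from pairwise estimation;
empty leading/trailing categories become ±∞ sentinel thresholds, which
the CDF handles exactly. Missing data use pairwise-complete observations.
If sampling noise makes the assembled matrix indefinite it is smoothed by
eigenvalue clipping at 1e-8 and rescaled to unit diagonal, with a flag.

Pairwise estimation makes the matrix *subset-stable*: the submatrix for
any item subset equals what a fresh run on that subset would produce.
The short-form machinery exploits this by estimating the full-pool matrix
once and slicing it per candidate.

## Factor models and fitting

Nine configurations over the same items (ids used throughout): 1 =
one factor; 2 = two correlated area factors (self = Identity +
Self-direction, interpersonal = Empathy + Intimacy); 3 = four correlated
domain factors; 4/5 = bifactor with two/four orthogonal specifics; 6a/6b =
two area factors under a second-order factor (6a free, 6b equal
higher-order loadings); 7a/7b = the four-domain analogues; `shortform` =
7b on a 20-item subset. Identification fixes all factor variances at 1;
bifactor general and specifics are mutually orthogonal; hierarchical
factor covariance is routed exclusively through the second-order paths.
The 6a/6b and 7a/7b free-vs-equal distinction is a reconstruction chosen
to reproduce the published parameter counts (487/486 and 489/486 on 97
items under the "4 thresholds per item + structural parameters"
convention); it also reproduces the classic identification failure of a
two-indicator higher-order factor: with two free paths only their product
enters the implied moments, the moment Jacobian is rank-deficient, and
the fit is flagged `identified=False` — detected numerically via the
smallest singular value of the Jacobian at the solution (ratio < 1e-7).

Fitting minimizes the least-squares discrepancy
F(θ) = Σ_{i<j} w_ij (r_ij − σ_ij(θ))² over the unique off-diagonal
correlations (unit diagonal is enforced by the correlation metric, so
residual variances are implied, bounded implicitly by clipping loadings
at 0.999 and projecting bifactor communalities below 1−1e-6; bound-active
solutions carry a Heywood flag). Weights default to 1 (ULS); a DWLS
weight vector can be supplied, but the asymptotic covariance of the
polychoric estimates — and hence robust mean-and-variance χ² scaling — is
deliberately out of scope, so **absolute χ² values are not comparable to
WLSMV output**; model ordering and the incremental indices are.
Optimization is damped Gauss–Newton with analytic Jacobians per model
family, from the deterministic start (all loadings/paths 0.5), five
jittered restarts on non-convergence, tolerance 1e-10 on the discrepancy.
A batched variant for the constrained short-form model runs thousands of
candidate fits simultaneously through batched normal equations (~1 ms per
20-item fit), which is what makes exhaustive enumeration of a
194,481-subset pool and the 1,000-draw baseline practical on one CPU; the
batch and scalar paths agree to machine precision and the batch path
requires every candidate to share the items-grouped-by-domain layout.

χ² = (n−1)·F_min; the independence model (all correlations zero) supplies
the baseline for CFI = 1 − max(χ²_m−df_m, 0)/max(χ²_b−df_b, χ²_m−df_m, 0),
clamped to [0,1]; RMSEA = √(max(χ²_m−df_m,0)/(df_m(n−1))), an error for
saturated models; SRMR = root-mean-square residual correlation.
Classification: good iff CFI > .95 ∧ RMSEA < .05 ∧ SRMR < .08; acceptable
with CFI > .90; else poor. Note that under the ULS convention the χ² of a
correctly specified model typically falls *below* its df at these sample
sizes, so CFI = 1/RMSEA = 0 is the expected readout in the well-specified
regime rather than a suspicious perfection.

## Reliability

Ordinal alpha is standardized alpha on the polychoric matrix:
α = k·r̄/(1+(k−1)·r̄). Omega coefficients come from the standardized
loading solution (consistent with correlation-metric fitting): with
general loadings g, specific loadings s, uniquenesses θ = 1−g²−s²,
ω-total = ((Σg)²+Σ_f(Σs)²)/(…+Σθ); ωH replaces the numerator with (Σg)²;
ωHS for a domain scale uses only that domain's items with the general
contribution counted as unwanted variance. Higher-order fits are first
residualized Schmid–Leiman style (g = λγ, s = λ√(1−γ²)) — the only route
to ωHS from a hierarchical solution — after which the bifactor formulas
apply; the two routes agree to 1e-10 by construction and by test.
Correlated-factor models with more than one factor have no general
factor, so their omegas are reported as NaN rather than through any of
the conventions that print ω ≈ 1 for such models.

## Clinical validity and utility

Cohen's d uses the df-weighted pooled SD. Adjusted R² regresses the
binary group indicator on the sum score (matching the "variance
explained in discriminating groups" reading; one predictor, so
adj R² = 1−(1−R²)(n−1)/(n−2)). AUC uses the Mann–Whitney rank identity
(ties ½) with a Hanley–McNeil confidence interval (DeLong is not
implemented). The Youden cutoff maximizes sensitivity + specificity − 1
over all attainable thresholds under the decision rule "score ≥ c ⇒
flagged", computed in integer arithmetic so exact ties are broken
reproducibly toward the smallest cutoff (favoring sensitivity). T-scores
are 50 + 10·(raw − mean)/SD normed on the healthy-control sample (the
norm group is configurable; the control sample is the defensible default
when no population norms exist).

## Ant colony optimization

Per iteration, 30 ants each draw 5 items per domain without replacement
with probability proportional to pheromone (initial level 1). Candidates
are scored by the sum of three logistic gates φ(x) =
1/(1+exp(−direction·(x−center)/scale)):

| component | inputs | center | scale | direction |
|---|---|---|---|---|
| φ_fit | mean of φ(CFI), φ(RMSEA) | .95 / .05 | .01 / .01 | + / − |
| φ_reliability | mean of φ(min domain ω), φ(min loading) | .80 / .40 | .05 / .05 | + / + |
| φ_validity | φ(adj R²) | .30 | .05 | + |

The CFA behind φ_fit is the equal-higher-order-loading hierarchical
model on the candidate's polychoric submatrix; min domain ω is the
minimum across the four domain-scale ω-totals from the Schmid–Leiman
split; a non-converged fit scores 0. The exact transform parameters and
update constants of the original application are not public, so these
are explicit reconstructions, chosen once: each gate centered on the
conventional quality threshold of its criterion, evaporation rate 0.1,
elitist deposit (the iteration's best candidate deposits its total score
on its items), pheromone floor 1e-6. The run stops after 20 consecutive
iterations without strict (>1e-9) improvement of the best total, or 500
iterations. Candidate evaluations are cached by item subset, so
re-sampled duplicates are free, and the whole run is deterministic under
a fixed seed (single process; no parallel colonies).

The random benchmark draws i.i.d. uniform quota-respecting subsets
(duplicates allowed) and scores them with the identical machinery;
non-converged draws are excluded and counted. The default is 1,000
draws — a desk-scale stand-in for the 10⁵-draw benchmark a computing
cluster affords — with the full per-draw table retained for scatter
plots. `combination_count` gives the exact search-space size in integer
arithmetic (≈ 4.1·10¹⁸ for the default pool), the quantity that rules
out exhaustive search.

## Numerical and design choices

* Polychoric optimizer: bounded Brent, |ρ| ≤ 0.9995, xatol 1e-7.
* CFA: deterministic start 0.5; LM damping ×10 on rejection, ×0.2 on
  acceptance, floor 1e-10; convergence when the discrepancy change is
  < 1e-10·(1+F) and the step < 1e-7.
* Identification tolerance: smallest/largest singular value of the
  weighted moment Jacobian > 1e-7.
* Youden ties: smallest optimal cutoff; AUC ties: ½ per the rank formula.
* Problem sizes in the test suite: the exhaustive-oracle pool uses 7
  items per domain (21⁴ = 194,481 candidates, scored in full); the
  dominance check runs the default 97-item pool with 800 respondents
  (640/160, preserving the study's ~4:1 control:patient ratio) and 1,000
  baseline draws. These sizes exercise every code path at full
  dimensionality while keeping a complete run in minutes.

## Known limitations

* No robust (mean-and-variance-adjusted) χ²; absolute χ² and RMSEA are
  convention-specific. No standard errors or modification indices.
* ωHS values for correlated-factor models are undefined here by design.
* The generator's clean simple structure makes random 20-item subsets fit
  well (baseline CFI ≈ 1); on real data the fit contrast between
  optimized and random subsets would be larger, while the validity
  contrast reproduces cleanly.
* Observed group separation (d ≈ 1.8–1.9 at default loadings) is
  attenuated relative to the latent δ = 2.1 by imperfect loadings and
  ordinal coarsening; stronger loadings push d above 2 as the
  clinical-utility property tests document.
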