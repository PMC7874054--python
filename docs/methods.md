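# Methods

## Scope and model

`ddmpriors` turns a corpus of published Diffusion Decision Model (DDM)
parameter estimates into informative prior distributions. The package
covers five concerns: (1) a validated data model and delimited-text I/O
for estimate corpora; (2) canonicalization of reporting conventions;
(3) constrained maximum-likelihood fitting of truncated and mixture
densities with Akaike-weight selection; (4) a synthetic-corpus
generator with known ground truth; (5) orchestration, serialization,
and a small prior-predictive simulator. Out of scope by design:
literature search and reference management, manual error-checking
judgments (exposed only as validation flags), multivariate/correlated
priors, and precision-weighted meta-analytic pooling (the uncertainty
information needed for weighting is typically not reported, so pooled
values are equally weighted).

## Corpus format

UTF-8 delimited text (comma default, tab accepted) with header

```
article_id, study_id, condition_id, participant_id, kind, value,
s_reported, software, rt_unit, reporting_level, constraint_group,
n_participants, task, population
```

`kind` ∈ {v, a, z, zr, ter, sv, sz, szr, ster}; empty string means
unknown/absent. Rows sharing (study_id, kind, constraint_group) — and
participant_id for individual rows — report one constrained parameter
repeated across conditions. Reading enforces uniqueness of
(article, study, condition, participant, kind) and row invariants;
writing round-trips exactly (floats serialized via `repr`).

## Canonicalization

Canonical scale: diffusion coefficient s = 1, seconds, relative
starting point, accuracy-coded drift. Stage order (each stage appended
to a per-row audit log):

1. **resolve_s** — explicit value → software default (DMAT 0.1; HDDM,
   fast-DM 1) → caller-supplied list of article ids following the 0.1
   convention → otherwise excluded with a logged reason. The corpus
   schema has no author column, so author-based conventions enter
   through that explicit id list.
2. **infer_units** — per article, from reported magnitudes: the
   non-decision parameters are in seconds iff the smallest T_er < 5;
   the remaining parameters are in seconds iff the smallest
   per-condition E(RT) = (a − z)/v < 10 (z taken as z_r·a if only bias
   is reported, a/2 when no starting point is reported; drift enters in
   absolute value because signs follow arbitrary response codings;
   condition-level medians are used). The minimum across conditions is
   the conservative choice against misclassifying slow-RT studies.
   Assignments are per parameter group, so the "T_er in milliseconds,
   rest in seconds" dialect resolves correctly. Unresolvable steps fall
   back to the declared or software-default unit and are flagged.
   Known limitation: a single-condition article with a very small
   drift rate can exceed the E(RT) threshold and be misread as
   milliseconds (~1% of generated articles); the underlying studies
   resolved such cases by manual checks, which are out of scope here.
3. **to_seconds** — times ÷ k (k = 1000); with s held fixed the
   diffusion scaling law gives v, s_v × √k and a, z, s_z ÷ √k;
   dimensionless kinds unchanged. This is the unique transformation
   preserving the first-passage process with fixed s; it is validated
   in the tests against a closed-form Wiener mean-exit-time oracle
   (E[T] must scale by 1/k) and guarantees E(RT) consistency.
4. **rescale_s** — accumulation-scaled kinds × (1/s_reported).
5. **relative_start** — z → z/a and s_z → s_z/a using the boundary
   separation matched on (study, condition, participant); unmatched
   rows are excluded with a logged reason.
6. **accuracy_code** — v → |v|.
7. **plausibility** — theoretical-bound screening (a ≤ 0, T_er < 0,
   z_r or s_z_r outside [0, 1], negative variabilities; zero is
   attainable for T_er and the variabilities and is never flagged).
   Violations are excluded at this configurable stage, never silently;
   flag computation itself is pure.
8. **dedup** — one representative per (study, kind, constraint_group
   [, participant]), the first after a deterministic
   (article, study, condition) sort, so results do not depend on file
   row order.
9. **average** — individual rows averaged (arithmetic mean) within
   (study, condition, kind); aggregated/group-level rows pass through.
10. **mirror** (pooling, bias only) — the pooled z_r sample becomes
    {x} ∪ {1 − x}: direction of bias is arbitrary across articles, so
    the mirrored sample removes direction, retains variability, and has
    mean exactly 0.5. Both the pre- and post-mirror counts are
    reported, since conventions for quoting the bias sample size vary.

## Candidate densities and fitting

Per parameter kind the candidate set respects the theoretical bounds:
on [0, ∞) the five single families (truncated normal, lognormal,
gamma, Weibull, truncated Student's t) and four mixtures (gamma+gamma;
truncated normal + {gamma, lognormal, truncated normal}); on [0, 1]
(z_r, s_z_r) truncated normal and truncated t plus the same four
mixtures truncated to [0, 1] (Weibull and the other positive families
are not offered as singles on the unit interval). Truncated densities
are the untruncated form renormalized by the interval mass; truncation
bounds are fixed constants of the kind and are not counted as free
parameters, giving k = 2 for truncated normal/lognormal/gamma/Weibull,
3 for truncated t (location, scale, and df are all estimated; fitted
df below 1 is allowed), and k₁ + k₂ + 1 for mixtures.

Fitting maximizes total log-likelihood in an unconstrained
reparameterization (log for positive parameters, logit for the mixture
weight) with Nelder-Mead local searches from multiple starts: a
moment-matched start, deterministic auxiliary starts (a large-df start
for truncated-t templates so the near-Gaussian limit is reachable, and
out-of-interval "skewed" location starts for truncated location
families, whose ML location can legitimately sit outside the support),
then seeded Gaussian perturbations; the incumbent is polished by one
restart from the optimum. Start sequences are prefixes of one seeded
stream, so the best-of-n log-likelihood is non-decreasing in the number
of starts. Defaults: 20 starts for a standalone fit, 10 inside the
pipeline; convergence tolerances 1e-8 (objective) / 1e-6 (parameters).
A candidate assigning zero density to a data point (e.g. lognormal
against an exact zero — zeros are retained in the data, never edited)
ends with log-likelihood −∞ and is reported non-converged, never
raised.

Numerical safeguards in the fit objective, each closing a route by
which the optimizer can turn floating-point artifacts into apparent
likelihood:

- component spread floored at 1e-3 × sample SD (degenerate spike
  solutions: with free df the likelihood is otherwise unbounded);
- df ≤ 1000 and gamma/Weibull shape ≤ 1e6 (beyond these the families
  are numerically indistinguishable from their Gaussian limits while
  `gammaln` cancellation turns log-densities into rounding noise);
- interval mass computed via survival functions when the support lies
  in the upper tail, and required to exceed 1e-9 (a support interval
  holding less untruncated mass than that has no significant digits in
  its renormalization).

Model choice uses Akaike weights wAIC_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2),
Δ_i = AIC_i − min AIC, computed over converged fits (non-converged fits
get weight 0 and are excluded from the normalization). Ties break
deterministically: fewer free parameters, then a fixed family/mixture
enumeration order. When a mixture wins, the component with the larger
weight (components are relabeled post-fit so the reported weight is
≥ 0.5; an exact 0.5 tie goes to the smaller-spread component) is
proposed as the single-family prior, with the weight recorded; single
families carry no weight. The mirrored-bias location is fitted freely —
symmetry of the data forces it to ≈ 0.5, and the deviation serves as a
diagnostic rather than being pinned.

## Synthetic corpora

The generator draws canonical values from per-kind "true" priors —
defaulting to the synthesis results of the published literature review
(truncated normal (1.76, 1.51) for v; gamma (11.69, 0.12) for a;
truncated t (0.5, 0.05, df 1.85) on [0, 1] for z_r; truncated t
(0.44, 0.08, df 1.32) for T_er; truncated normal (1.36, 0.69) for s_v;
truncated normal (0.33, 0.22) on [0, 1] for s_z_r; truncated t
(0.17, 0.04, df 0.88) for s_Ter) — and un-canonicalizes them per
article. Defaults, chosen once to emulate the surveyed literature:
158 articles (the number of usable references in the survey), 1–4
conditions and 10–40 participants per study, 40% of articles on the
s = 0.1 scale, 15% fully in milliseconds plus 10% reporting only the
non-decision parameters in milliseconds, 5% reporting individual
estimates (8 of 158 surveyed articles did), the three across-trial
variability parameters constrained across conditions, 2% multiplicative
outlier contamination with factor 3 (a minimal model of the
non-standard tasks, special populations and reporting errors that
motivate mixture candidates), drift signs flipped with probability 0.1,
s reported explicitly in 70% of articles (software-implied otherwise),
and a per-study random bias direction so mirroring is exercised
nontrivially. All randomness flows from a single seed;
identical configurations produce byte-identical corpora.

Every canonical value is recorded in a ground-truth ledger keyed by
(study, condition, kind) after deduplication/averaging, so
`round_trip_check` can generate, canonicalize and compare: with no
outliers and correctly re-inferred conventions the maximum discrepancy
is at floating-point level (< 1e-15 observed; < 1e-9 asserted). The
reported discrepancy conditions on convention recovery, with the
unconditioned maximum and the mismatch count reported alongside.

What the generator does *not* emulate: correlations between parameters
within studies, task- or population-dependent true priors (available
explicitly via configuration), non-multiplicative reporting errors,
digitization noise from figure extraction, and publication bias.
Passing tests therefore demonstrate correctness of the pipeline's
bookkeeping and estimator behavior under the modeled heterogeneity,
not robustness to every failure mode of real literature data.

## Selection consistency: what to expect at which sample size

With pools of n ≥ 5000 values drawn from a single candidate family,
wAIC selection recovers the generating family (or a mixture it
dominates) reliably; this is asserted in the suite. On a 200-article
corpus the variability-parameter pools hold only ~200 values, and
there selection is intrinsically noisy: a truncated t beats a true
truncated normal in roughly 15% of clean replicates (the extra df costs
one AIC point and the boundary likelihood-ratio upset rate does the
rest), and the mirrored bias pool — duplicated values plus symmetrized
contamination — systematically favors a symmetric truncated-normal
mixture over the generating truncated t. The end-to-end
family-recovery test documents this regime; across generator seeds the
200-article recovery count ranges from 4 to 7 of 7.

## Pipeline, priors, prediction

`run_review` executes the stages above, pools each canonical kind
(optionally filtered by task/population tags), fits the candidate set
(kinds with fewer than `min_n` = 10 pooled values are marked
unfit-able rather than fitted), selects, and assembles a prior table
with the full per-kind candidate report (family, parameters,
log-likelihood, k, AIC, wAIC, convergence) and an audit of counts at
every stage. Everything is deterministic given the seed; per-kind fit
seeds derive from one `SeedSequence`. JSON serialization round-trips
losslessly; CSV mirrors the conventional prior-table layout (kind, N,
distribution, weight, location/shape, scale, df, truncation and
empirical bounds, with an empty weight for single families).

`sample_prior` draws by inverse-CDF restricted to the truncation
interval. `prior_predictive_rt` simulates first-passage times by Euler
discretization (increments of mean v·dt and SD s·√dt from z = z_r·a to
absorption at 0 or a; RT adds T_er) with dt = 1e-4 s by default and a
30 s cap (censored trials are counted, not silently dropped). The
discretization bias of the mean RT is O(√dt); the simulator is a
sanity tool, not a fitting engine. At s = 0 the deterministic limit
T_er + (a − z)/v is returned exactly. The simulator is verified against
the closed-form Wiener mean exit time
E[T] = −z/v + (a/v)·(1 − e^{−2vz/s²})/(1 − e^{−2va/s²}).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 10,000 draws × 20 seeds
for single-family parameter recovery (each parameter within 5% relative
error in ≥ 19/20 replicates), 5000-value pools for large-sample
selection consistency, one 200-article corpus for end-to-end family
recovery, a 158-article corpus for the exact round trip, and 4000
trials for the first-passage oracle comparison — sizes chosen so each
check is decisively informative for its tolerance.
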