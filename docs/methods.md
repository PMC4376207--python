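# Methods

This note documents the models, parameter choices and numerical conventions
behind `portaltypes`, and what the synthetic validation does and does not
establish about real portal data.

## Sessionization model

Events are point instants (login, logout, function click) per patient. A
session opens at a login, or at an *orphan* click with no open session —
real web logs lose login records, and discarding orphan clicks would break
click conservation, so orphans open an implicit session instead. A session
closes at the first explicit logout, or when the gap to the next event
strictly exceeds the inactivity timeout (default **20 minutes**). A
timed-out session ends at its *last observed activity*: we do not add the
idle tail (nor a fixed 20-minute penalty) to the session length, since the
patient demonstrably did nothing in that interval. A logout arriving when
no session is open (stray, or after a timeout already closed the session)
is ignored with a logged warning.

Sessions separated by at most the merge gap (default **3 minutes**,
boundary inclusive) are combined transitively into one activity instance;
the inter-session gap *does* count toward the merged length, because the
merged unit is interpreted as a single visit interrupted by a re-login.
Classification into active users (≥ 2 merged sessions in the window) vs
non-users uses post-merge counts; the study window is half-open
`[start, end)` so boundary events belong to exactly one window.

Page-view lengths are click-to-next-click intervals; the final click's view
is measured to the logout instant when the session ended by logout, and
omitted after a timeout (no observed endpoint). A session with a single
click and a timeout therefore contributes no view — patients with no
measurable view anywhere get `avg_view_mins = 0` plus a flag rather than a
missing value, keeping the feature matrix complete.

## Usage variables

The 41-column matrix is: `sess`, `hitdays`, `hitmo`, `avg_sess_len_mins`,
`tot_len_mins`, `avg_view_mins`, `totfxn`, `avgfxnses`, `adminfxn`,
`carefxn`, `ratioac`, then the 30 per-function counts in vocabulary order.
A session counts toward the hit-day and hit-month of its start instant; a
session spanning midnight contributes one hit-day. `hitmo` is bounded by
the 12 months of the window.

The administrative set defaults to the appointment, directions,
provider-detail, proxy, referral, customer-service and record-keeping
functions (`appt_final`, `drivingdirections`, `providerdetails`,
`proxyaccessview`, `switchcontext`, `referralreview`, `referralrequest`,
`addresschangerequest`, `customerservicerequest`, `demographics`,
`personlpreferences`); everything else is care-related. Because reasonable
analysts could classify one or two of these differently, the set is a
config parameter rather than a constant. `ratioac = adminfxn / carefxn`;
when a patient has zero care clicks the denominator is floored at 1 and the
profile flagged, which keeps the matrix finite without imputation.

## Factor analysis

Columns are z-scored (sample SD, ddof = 1); unscaled counts would let
high-volume functions dominate the principal components, so
standardization is the default but remains a switch. Extraction is
principal components of the correlation matrix; loadings are eigenvectors
scaled by the square roots of their eigenvalues. Rotation is varimax with
Kaiser normalization (rows scaled to unit communality during rotation),
iterated to a 1e-10 relative tolerance; communalities are invariant under
the rotation to ~1e-15. Factor scores use the regression method,
`scores = Z R⁻¹ L`, the standard default for component scores. Two
conventions make the solution fully deterministic: each rotated factor's
largest-magnitude loading is made positive, and factors are ordered by
explained variance. The number of factors defaults to **10**; zero-variance
columns are a named error at this level, while the pipeline driver drops
them first (they can occur in small subsamples and carry no information).

## Clustering and model selection

Ward's minimum-variance linkage on the factor scores (scipy's
implementation; merge height h relates to the within-SS increase by
ΔSSE = h²/2). Cuts are relabelled 1..k by descending cluster size so
reports are stable across runs.

Outliers are removed before the reduction: patients whose session count
strictly exceeds the cohort's 99th percentile. The percentile is
nearest-rank (type 1) — reproducible and never a fractional threshold. Note
that under nearest-rank at most `n − ceil(0.99 n)` observations can exceed
the threshold (22 in a cohort of 2282), so the exclusion count is a
property of the rule, not a tunable.

The number of clusters is guided by two diagnostics computed for every
candidate k (default 2–15):

* **CCC** (cubic clustering criterion, Sarle's formulation): compares the
  observed R² of the k-cluster partition with its expectation under a
  uniform distribution on a hyperbox aligned with the data's principal
  axes, with the between-cluster dimensionality p* capped at min(p, k−1).
  Values near or below zero indicate no structure; on a single Gaussian
  cloud the criterion stays negative for all k.
* **pseudo-t²** (Duda–Hart): for the merge joining clusters A and B,
  ΔSSE / ((W_A + W_B)/(n_A + n_B − 2)). A sharp jump at a merge says the
  two clusters being joined were distinct.

The automatic rule selects, among local CCC peaks, the k with the largest
positive pseudo-t² jump (t² of the merge going below k minus t² of the
merge that formed k), falling back to the global maximum jump. Merges of
two singletons have an undefined denominator and are scored 0 at height 0
(+∞ otherwise). The full table is always emitted: the criteria are a guide,
and the analyst can pin k explicitly.

## Validation

Subsample stability reruns the whole chain (outlier filter → factors →
Ward → k selection → cut) on random subsamples without replacement
(default 10 subsamples of 50%) and scores agreement with the full-cohort
labels on the shared retained patients by adjusted Rand index; the
agreement statistic and the 50% fraction are package choices. K-means
replication re-clusters the same factor scores at the hierarchical k (best
of 50 starts by within-cluster SS) and reports ARI plus a best-match
confusion matrix (columns matched by linear assignment). Both reports
serialise to sorted-key JSON so fixed-seed reruns are byte-identical.

## Synthetic-data generator

Each archetype is: a per-month activity probability (consistency), a
shifted Poisson (≥ 1) for sessions per active month (frequency) and clicks
per session (intensity), a multinomial over the 30 functions (signature),
log-normal inter-click minutes (σ = 0.8, mean 0.5–1.4 min across
archetypes, truncated below the 20-minute timeout so a generated session
never splits), a 0.7 probability of explicit logout, and a 0.1 probability
of an immediate (≤ 3 min) re-login that exercises the merge rule. Session
start times are uniform within the month (no diurnal model — the pipeline
uses no time-of-day features). The eight defaults differ in rate
parameters (expected sessions from ~8 to ~58 per year) and in signature
functions boosted to at least 3× their weight in any other archetype; only
the appointment-preparer's expected administrative use exceeds its
care-related use. Demographics are drawn per archetype (the proxy type is
younger and predominantly female) but never feed the clustering.
Closed-form expectations (E[sess] = p_month × 12 × E[sessions/month], etc.,
assuming independence and counting merged re-login continuations) are
exposed for calibration checks and agree with Monte-Carlo means within 2%
at n = 4000.

What passing on synthetic cohorts shows: the pipeline recovers planted,
moderately separated behavioural types (modal selected k = 8; ARI ≥ 0.9
against truth across 10 seeds at the default 8 × 50 scale) and is stable
under subsampling and algorithm replication. What it does not show: real
portal users need not fall into well-separated types — real logs have
diurnal and weekly rhythms, correlated function choices within sessions,
overdispersed counts and secular trends that the generator deliberately
omits. Results on real data therefore still require the diagnostic table
and validation reports, not just the automatic k.

## Problem sizes and determinism

Default experiment sizes — 8 archetypes × 50 patients (+ 20 non-users),
10 recovery seeds, 10 subsamples at 50% — were chosen so a full validation
cycle runs in about half a minute on one CPU while keeping every cluster
comfortably larger than the factor dimension. A single config-level seed
drives the generator, subsampling and k-means starts; all remaining steps
are deterministic by construction (stable sorts, lowest-index tie-breaks,
fixed sign conventions).
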