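# Methods

## The marginal-value model

The package operationalizes the marginal value of one additional biodiversity
sampling event (BSE) as its **expected leverage** under the project's target
statistical model. Three assumptions are load-bearing:

1. *The project's goal is a regression.* The default target is a
   binomial-logit detection model (detected 0/1 per BSE on environmental site
   covariates) — the canonical species-distribution setting. A Gaussian
   family is provided for abundance-style responses and for exact algebraic
   tests. No regularization is offered: the leverage identities
   (0 ≤ h_i ≤ 1, Σh_i = p) are exact only for unpenalized fits.
2. *Past leverage is predictable from forward-looking covariates.* Leverage
   for a GLM is taken at IRLS convergence from the weighted design,
   h = diag(W^½X(XᵀWX)⁻¹XᵀW^½), computed via the reduced QR of W^½X (no n×n
   matrix is ever formed). Each historical event's hat value is paired with
   the five covariates its site had *immediately before that event*
   (time-matched rows; same-day events are mutually invisible), and an OLS on
   transformed covariates is fit. The R² of this regression is typically
   small — leverage is dominated by the environmental design, which is
   deliberately excluded because it is not forward-looking — and the forecast
   only relies on the systematic spatio-temporal component.
3. *Value is relative.* Raw forecasts are min–max normalized over the
   candidate set and ranked; all downstream incentives consume normalized
   values, so any affine rescaling of the forecast is irrelevant (asserted by
   property test).

## The five covariates and their treatment

| covariate | units | transform | censoring |
|---|---|---|---|
| sampled | 0/1 | identity | — |
| dist_nearest_sampled | m | log1p | grid diagonal when nothing sampled |
| median_interval | days | log1p | H when < 2 events |
| neighbor_median_interval | days | log1p | H when the nearest sampled *other* site has < 2 events, or none exists |
| days_since_last | days | log1p | H when never sampled |

H = 2 × the desired sampling interval (default 14 days, so H = 28). Censoring
at a finite horizon keeps never-sampled sites attractive to the model without
infinities; censored fields carry explicit flags. The log1p transform encodes
saturation of leverage–distance/recency relationships and is swappable per
covariate through the stored transform spec. "Nearest neighbor" means the
nearest *sampled* site excluding the site itself (ties broken by ascending
site index); the alternative reading — nearest grid neighbor regardless of
sampling — would make covariate 4 degenerate with covariate 3 on mostly
unsampled grids. Timestamps are truncated to whole UTC days; distances are
center-to-center planar distances on an equirectangular projection about a
local anchor, adequate for the local-to-regional extents the package targets.

Degenerate normalization: when every candidate has the same raw value (cold
start, intercept-only model) there is no information to rank on and every
site receives normalized value 0.5 — the midpoint avoids manufacturing fake
extremes. Ranking ties break by ascending site id, making every surface
deterministic and auditable.

## The synthetic world

The generator emulates semistructured citizen-science data: smooth
environmental covariates (standardized sum of a fixed linear gradient and a
3×3 moving-average Gaussian noise field — cheap spatial autocorrelation,
nothing more), logistic occupancy `psi = expit([1, env]·beta)` with a single
static Bernoulli draw per site, imperfect detection, and observers whose site
choice follows exp(−d/λ) from a home point — convenience sampling.
Non-detections are retained as `NONE` checklist rows so the 0/1 response is
defined for every event. All randomness flows from one seed through
`SeedSequence` stream splitting (landscape / occupancy / history / homes), so
each stage is independently reproducible.

Reference study conditions (fixed defaults, used by the tests and the
acceptance script):

- 30 × 30 grid of 100 m cells; 2 environmental covariates;
  beta = (0, 1, −0.75); detection probability 0.6
- 12 observers, homes uniform over the grid; haphazard λ = 100 m (one cell —
  the "walking the dog" regime of strong home bias)
- guided policy: softmax temperature 0.1 over normalized values within a
  2000 m agent radius (stochastic compliance, not perfect obedience);
  surface refit cadence 14 days; comparison horizon 200 days
  (12 × 200 = 2400 BSEs per arm, equal effort by construction)

What the generator does **not** emulate: observer skill heterogeneity,
taxonomic preferences, weather/time-of-day effects, travel routes, drop-out,
or multi-species checklists. Tests passing on this world show the machinery
is correct and that the guided/haphazard contrast behaves as designed; they
do not show that real volunteers would comply, nor how strong the effect
would be in any real project.

## Closed loop and cold start

The simulation alternates daily agent steps with cadence refits of the whole
pipeline (target GLM → leverage → value regression → surface). Until the
first refit, and whenever a refit is impossible (single-class response,
collinear design from too-concentrated sampling), the surface falls back to
uniform — guided agents then explore their radius uniformly at random. A
surface older than the cadence raises an error rather than silently steering
agents with stale values. Surfaces at every refit are retained for
provenance; identical config + seed reproduces histories byte for byte.

## Evaluation metrics

- **mean_nn_distance** (m): mean over *all* grid sites of the distance to the
  nearest sampled site — spatial coverage.
- **median_interval_median** (days): median over all sites of the per-site
  median sampling interval, with sites having fewer than two events censored
  at the observation span (not at H: for an outcome metric, a never-revisited
  site must register as worst case, whereas the covariate-side censor H
  exists to keep such sites *attractive*). Both arms are evaluated on the
  identical full site set.
- **occupancy_rmse**: a fresh detection GLM is fit to the final history; its
  fitted recording probability is divided by the known detection probability
  and clipped to [0, 1] to land on the occupancy scale, then compared by RMSE
  to the true psi surface.

Under the reference conditions guided sampling wins spatial coverage in
essentially all paired replicates and the interval metric in a clear
majority; the interval margin is the more fragile of the two, because it
requires the guided arm to push more than half the grid to two or more
visits within the horizon — replicates with unfavorable home placement can
leave the guided median censored. Replicates where this happens are reported
as losses, not excluded. The occupancy-RMSE contrast is the weakest claim
and is reported rather than guaranteed: it depends on how much of the
landscape's environmental range haphazard sampling already covers.

## Numerical choices

- GLM fitting delegates to statsmodels IRLS (tolerance 1e-8, max 50
  iterations); degenerate (all-0/all-1), separated (|linear predictor| > 30
  at the optimum), or non-converged fits raise typed errors — leverage is
  never extracted from a questionable fit. Design covariates are standardized
  with training statistics stored on the model so candidate-site prediction
  reuses identical scaling; rank deficiency is reported with the offending
  columns named.
- Hat values: reduced QR, h_i = Σ_j Q_ij²; the trace identity is asserted at
  1e-8 on every extraction. The brute-force full hat matrix lives in the
  package only as a test oracle.
- Grid cells are half-open [x, x+Δ)×[y, y+Δ), so boundary points belong to
  exactly one cell; site ids are "ix_iy" with the origin at lower left.
- Points: proportional to normalized value (p_max × v, default p_max = 100),
  so an opportunistic BSE anywhere still earns in proportion to its site's
  potential; a rank-linear ladder ships as an alternative scheme. Points are
  a pure function of site and surface — species never enters. Leaderboard
  density is the count of opted-in participants whose centers fall within a
  participant's own radius (self included, so density ≥ 1).
- Exclusion masking tests site *centers* against polygons — deterministic and
  unambiguous at grid scale; polygon-intersection semantics would make
  partially covered cells ambiguous.

## Known limitations

- One pooled target model over the full history; per-window leverage is not
  implemented (the window length is exposed in config only through the refit
  cadence).
- One focal species; multi-species valuation is out of scope by design
  (points reward looking, not finding, precisely so that species identity
  cannot be gamed).
- The equirectangular planar frame is inappropriate for continental extents;
  the projection is a stated approximation, not a CRS library.
- The expected-leverage regression is a linear probe; if a project's leverage
  structure is strongly non-linear in the five covariates, the transform spec
  is the only lever currently exposed.
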