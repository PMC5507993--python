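# Methods

`passnet` reimplements, as a tested pipeline over synthetic data, a
notational-analysis workflow for association football: offensive plays are
cut out of a match event stream, classified by outcome, aggregated into
directed ball-passing networks per match period, summarized by three
social-network metrics, and entered into a two-block hierarchical logistic
regression that asks whether the metrics predict play success over and above
pass volume.

## Play segmentation and outcome classes

A team is considered in possession once it completes a pass and keeps the
ball afterwards, so an offensive play starts at the first completed pass of a
possession and ends at a shot, a loss of possession (loss event or
incomplete pass), the opponent's next completed pass, or the half-time
whistle. Kickoff possessions are ordinary open play.

Outcome classes:

* **SOP** (successful): the play contains a shot at goal, or any
  possession-held event (pass, reception contact, shot attempt) located in
  the finishing zone — zone 4 of the four equal longitudinal pitch zones
  coded in the attacking team's direction. A bare loss event in zone 4 does
  not qualify: the ball arrived without being controlled there.
* **neutral**: set-piece-initiated plays whose finishing-zone access is not
  earned in open play — corner kicks, throw-ins, and free kicks whose first
  pass is received directly in zone 4 — unless they end with a shot; plus
  plays truncated by the half-time whistle with the ball retained and no
  success criterion met. Neutral plays are excluded from all networks.
* **UOP** (unsuccessful): everything else, i.e. possession lost below the
  success criteria.

The ordering of these checks is deliberate: a shot always wins; the
set-piece screens are applied *before* the zone-entry criterion, because a
zone-4 entry granted by the set piece itself (e.g. a free kick dropped into
the box) is exactly what the neutral class exists to remove, and applying
the zone criterion first would make the free-kick clause unreachable.

Each half is divided into three fractions of its own full duration
(stoppage included), giving six match periods; a play belongs to the period
containing its first event. Fraction boundaries are half-open
`[lower, upper)` with the final fraction closed at the half's end — a play
starting exactly on a boundary belongs to the later fraction. Only relative
position within the half matters, so the rule is invariant to uniform time
rescaling.

## Networks and metrics

Per match, plays are aggregated into exactly 24 networks: 6 periods × 2
teams × {SOP, UOP}. Empty cells are materialized as all-zero networks so
the 24-per-match contract is structural; zero-pass successful networks are
later dropped at screening, the counterpart of removing "no passes" cases
from a real dataset. The node set is always the 11 tactical positions
(substitutes inherit the position number); every completed pass increments
one weight cell, and a *link* is a binary ordered passer→receiver pair with
at least one pass.

With n = 11 fixed and L the number of links:

* **Density** Δ = L / (n(n−1)) ∈ [0, 1]. Binary: repeated passes add no
  density.
* **Average local clustering** C̄ = (1/n) Σᵢ Cᵢ with
  Cᵢ = |{a_jk among neighbors of i}| / (kᵢ(kᵢ−1)), the neighborhood being
  the union of in- and out-neighbors and the numerator counting directed
  links among them; Cᵢ = 0 when kᵢ < 2 (the 0/0 case). Isolated positions
  therefore dilute both density and clustering — intended, since n is fixed.
* **Freeman degree centralization**
  C_D = Σᵥ (deg(v*) − deg(v)) / (n² − 3n + 2), with degrees taken on the
  symmetrized binary graph so the denominator (n−1)(n−2) normalizes the
  star to exactly 1 and degree-regular graphs to 0. An alternative
  convention using in+out directed degree is available
  (`degree_mode="directed_total"`) for sensitivity checks; it can exceed 1
  (a reciprocated star scores 2) and is not the default.

## Screening and regression

The case table (one row per network: outcome 1 = SOP network, total passes,
three metrics) is screened in this order:

1. zero-pass successful networks removed (unsuccessful zero-pass cases are
   kept);
2. z-score outlier screen on the predictor columns, strict |z| > 3.29 with
   sample SD (a case exactly at the threshold is kept);
3. Belsley collinearity diagnostics: the design (intercept included) is
   column-scaled to unit length; condition indexes are σ_max/σ_k from its
   SVD; variance-decomposition proportions (v_jk/σ_k)² normalized per
   variable; a dimension is flagged when its index exceeds 30 *and* at
   least two variables load > 0.5 on it. Exact rank deficiency reports an
   infinite index and flags the involved variables. Reported, not acted on.
4. Box-Tidwell linearity-of-the-logit: one logistic fit with all predictors
   plus each x·ln(x) interaction; linearity passes when every interaction's
   Wald p exceeds 0.05. Because the metrics can be exactly 0, a predictor
   with nonpositive values is shifted by +1 inside the interaction term
   (documented, switchable; `shift="none"` raises instead).
5. the three metrics are rescaled ×10 to a 0–10 scale, so their odds ratios
   refer to a 0.1 change of the raw metric; a second rescale of the same
   frame is refused.

The hierarchical fit enters **total passes** alone in block 1 and adds the
three metrics in block 2, estimating the metrics' effect after controlling
for volume. Each block reports G = −2(LL_reduced − LL_full) against the
constant-only model; block 2 additionally reports its improvement over
block 1 (χ² with 3 df). G is additive across blocks by the likelihood
identity.

Fitting is maximum likelihood via iteratively reweighted least squares
(Newton-Raphson with step-halving), converged when max |score| < 1e−8 or
the relative log-likelihood change < 1e−10, within 100 iterations. Standard
errors come from the inverse observed information; Wald χ² = (β/se)² is
referred to χ²(1); odds ratios exp(β) carry normal-theory 95% intervals
exp(β ± 1.96 se). Quasi-separation is detected as a standardized |β| > 15
and raised as `SeparationError` by default (or flagged with
`on_separation="flag"`) — never silently returned as garbage estimates.

Diagnostics: Nagelkerke R² (Cox-Snell rescaled by its maximum), the
Hosmer-Lemeshow decile-of-risk test (equal-count quantile bins of the
fitted probabilities with ties unsplit, df = bins − 2, zero-expectation
bins merged with a warning — SPSS-comparable but not bit-identical, since
tie handling differs across packages), and a 0.5-cutoff classification
table reporting percent correct per class and overall.

## The synthetic-data generator

The simulator emulates the *statistical* structure the analysis assumes,
not football per se. Per match: two teams, half durations 2700 s plus a
uniform [60, 300] s stoppage draw (so the six periods genuinely differ in
length), and a Poisson number of alternating possession slots per half.
Each possession draws a chain skeleton — completion Bernoulli(0.85) per
attempt, continuation Bernoulli(0.85) per completed pass (≈3 completed
passes per possession), the receiver drawn from the team's preference
matrix. Preferences are one symmetric Dirichlet row per passer over the 10
teammates, drawn once per team per match; the concentration is the single
dial for link diversity and hence density, independent of pass volume.
Zones advance by at most one per reception with probability 0.35; set
pieces start 10% of possessions.

Play success is planted at the network level: for each (team, period) cell
the planted logit a + b·(cell total passes) + c·(pooled density × 10) with
default (a, b, c) = (0.4, 0.05, −1.1) gives a success probability, and
each of the cell's open-play possessions is independently designated
successful or not. Rendering then *realizes* the designation — successful
plays earn a zone-4 entry (shot with probability 0.4, else a controlled
touch followed by a loss), unsuccessful plays stay below zone 4 and end in
a loss — so the event stream, the ground-truth channel and the planted
probabilities are mutually consistent by construction, and segmentation
closure (100% recovery of boundaries, categories and periods) is a
meaningful oracle. Corner and throw-in possessions are rendered without
shots so they land in the discarded neutral class; a one-pass free kick
designated successful always ends in a shot, since a quiet zone-4 touch
straight off the kick would be a set-piece delivery, not an earned entry.
With `success_model=None` the generator runs in natural mode: zones advance
all the way to 4, a holder who stops passing dribbles on until the
finishing zone or a loss, and success emerges from the dynamics alone (in
the limit of certain completion and certain advance, every open-play
possession is successful).

Defaults were chosen once to give ≈120 possessions per match, realized
network densities spanning 0–0.35, and a roughly balanced SOP/UOP case
split after screening — the regimes the regression is meant to operate
over. With 12 matches a study yields the structural 288 pre-screening
cases.

What the generator does **not** emulate: spatial player tracking, tactical
formations, opponent pressure (possessions alternate deterministically),
deflections that return the ball to the attacking team, within-match form
changes, or any dependence between the two teams' styles. Passing tests on
this generator therefore demonstrates correctness of the pipeline's
bookkeeping and estimation — not that real match data satisfy the planted
model.

## Numerical and testing choices

* Tie-breaks and degenerate inputs: zero-variance predictor columns
  contribute no outliers; fewer than 10 distinct fitted probabilities merge
  Hosmer-Lemeshow bins and reduce df; an empty event log segments to no
  plays; an all-zero network scores 0 on all three metrics.
* The clustering implementation is checked against a brute-force
  neighbor-pair enumeration oracle on 1000 random 11-node digraphs; the
  IRLS engine against the closed-form 2×2 log odds ratio, a Nelder-Mead
  likelihood maximizer (agreement to 1e−5), and statsmodels as an
  independent cross-check.
* Monte-Carlo test sizes are the package's own trade-off between power and
  runtime: the case-level type-I calibration of the block-2 improvement
  test runs 1000 replicates at n = 288 (observed rate ≈ 0.049); the
  full-pipeline null calibration runs 60 replicates of 3-match studies; the
  pipeline-level recovery of the planted negative density effect uses a
  150-match study (fitted c ≈ −1.2 against planted −1.1); Box-Tidwell
  calibration uses 500 replicates at n = 300.
* At the network-case level the block-1 total-passes coefficient need not
  recover the planted b: a cell's successful and unsuccessful networks
  split the cell's passes, and with success probabilities below ½ the SOP
  network mechanically receives fewer passes — a selection effect of the
  case construction, not an estimation error. The directional claim tested
  is on the density coefficient.

## Known limitations

* The Hosmer-Lemeshow binning is quantile-based with ties unsplit and so
  is comparable to, but not bit-identical with, other implementations.
* Density, with n fixed at 11, is bounded above by total passes / 110;
  sparse cells therefore couple density and pass volume, which is visible
  in the collinearity diagnostics of small synthetic studies.
* The centralization and directed-clustering conventions used by
  point-and-click network tools are not fully documented by their vendors;
  both conventions here are explicit and the centralization degree mode is
  switchable for sensitivity analysis.
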