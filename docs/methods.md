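# Methods

## The scientific question

A decision-maker repeatedly chooses between two-outcome 50/50 gambles. Under
an *additive* wealth dynamic the drawn outcome is added to capital; under a
*multiplicative* dynamic capital is multiplied by the drawn growth factor.
The additive dynamic is ergodic — the expected per-round increment (ensemble
average) equals the per-round increment a single long-lived player
experiences (time average). The multiplicative dynamic is not: for a gamble
with factors m₁, m₂ the expected factor is (m₁+m₂)/2 while the time-average
growth rate is ½·ln(m₁m₂), and by AM–GM the latter can be negative while the
former exceeds 1 (factors 0.6/1.5: +5% expected gain, ln(0.9)/2 ≈ −5.27% per
round). The pipeline asks whether choosers under perceived time pressure
(intuitive responses) align with time-average optimization where ergodicity
is broken, by comparing the probability of choosing the lower-variance
("safer") bet between a timed and a control group in each dynamic.

## Wealth-dynamics simulator (`dynamics`)

Trajectories are simulated with one seeded `numpy` generator per ensemble;
draws are consumed round-major so the matrix is reproducible from the seed.
Capital is floating point; additive capital is *not* clamped at zero (the
design allows per-round losses up to 300, so temporary negative capital is
meaningful). Default demonstration bets are 0.6/1.5 multiplicative and
−100/+150 additive; both are arguments, not constants. Over very long
multiplicative horizons with negative drift, capital underflows to zero
around e⁻⁷⁴⁵; diagnostics that average log increments should use horizons
well short of that (the shipped analyses use ≤ 5·10⁴ drift units).

## Bet-couple generator (`betgen`)

A scored couple pairs a riskier and a safer bet with exactly equal expected
value and strictly ordered variances (two-point variance p(1−p)(hi−lo)²).
The riskier bet is drawn uniformly (by rejection) from the feasible region:

* additive — each outcome within ±300, expected value within ±100;
* multiplicative — each factor within [0.7, 1.4] and the bet's time-average
  growth factor √(lo·hi) within [0.945, 1.05].

The growth-factor band binds the riskier (seed) bet only; the safer bet must
respect the outcome box but may sit between the band's arms, which is where
the equal-EV locus passes. Outcomes are quantized — integers (additive),
hundredths (multiplicative) — and the safer bet's spread is then drawn
uniformly from the on-grid spreads strictly smaller than the riskier one's
with the parity that keeps both outcomes on-grid, so EV equality is *exact*
on the grid, not within a tolerance. Couples whose quantization leaves no
strictly smaller spread are resampled; a spread of zero (a sure payment) is
an admissible safer bet. Sampling densities (uniform over the region, then
uniform over admissible spreads) are a design choice; nothing downstream
depends on them beyond the audited constraints.

"No-brainer" attention checks are couples where one bet state-wise dominates
the other (every outcome at least as good, one strictly better). Dominance
implies unequal means, so no-brainers can never enter the equal-EV
estimation; the dominant bet is stored as the correct answer. Five such
couples per setting join 35 scored couples, indexed 1–40 (additive) and
41–80 (multiplicative), with the checks at 36–40 and 76–80.

The curvature argument that justifies the risk coding is implemented in
`check_lemma`: for an equal-EV couple with outcomes a < b ≤ c < d, Jensen's
inequality forces every monotone utility with concave curvature to weakly
prefer the inner (safer) pair, every convex one the outer pair, and linear
utility to exact indifference. The property suite sweeps random monotone
piecewise-linear utilities built as positive combinations of x ↦ min(x, t)
(concave) and x ↦ max(x, t) (convex) with knots inside (a, d), for which the
Jensen gap is strictly positive almost surely.

## Synthetic respondents (`agents`)

The deposited human data cannot ship here, so the generator *encodes* the
behavioural hypothesis rather than discovering it. Each agent scores a bet
with one of three models — `ev_indifferent` (ensemble average),
`time_average_optimizer` (time-average growth rate), or `isoelastic`
(expected isoelastic utility of one round's end wealth at a fixed reference
of 1000; respondents receive no capital feedback, so the reference never
updates) — and chooses by a logistic rule P(safer) = σ((v_safer −
v_riskier)/τ). Defaults: the timed group is a time-average optimizer with
temperature τ = 0.02 (in growth-rate units, giving safer-bet probabilities
of roughly 0.55–0.8 across the multiplicative couples), the control group is
ev-indifferent. Because every scored couple is EV-equal, the control group's
choice probability is *exactly* 0.5, and because additive couples share
their time average, so is the timed group's in the additive block — the
generated data therefore reproduce the study's qualitative pattern (group
difference in the multiplicative setting only) by construction. Alternative
mixes (e.g. identical agents in both groups, for null calibration) are
plain config options.

No-brainers are answered correctly with probability 0.78 (error rate 0.22),
matching the observed overall correctness. Respondent-level cumulative
response time is log-normal with the group's target median (defaults 579 s
timed, 694 s control) and a log-scale shape of 0.25 (timed) / 0.45 (control;
more dispersed); per-couple times split the total by a Dirichlet(8) draw.
Per-couple time structure in the real data is unconstrained — these
per-couple times are a modelling convenience and only their per-respondent
sums are analysed. The log-normal separation makes the group difference in
times somewhat crisper than in the human sample, where the Mann–Whitney
difference was marginal; the test's p-value under the defaults varies
widely by seed, and only its direction (timed faster) is a stable feature.

What passing tests on these data show: that the estimation and testing
machinery recovers known choice probabilities, controls its type-I error,
and detects the encoded pattern. What they cannot show: anything about real
respondents — heterogeneity across people, sequential effects, or the
description–experience gap are all absent from the generator.

## Quality control (`qc`)

A respondent is retained iff they answered ≥ 3 of 5 no-brainers correctly
in *each* setting (a per-setting conjunction; the boundary 3/5 + 3/5 is
retained). The filter is idempotent and monotone in correctness, and with
iid per-answer correctness 0.78 the retention rate converges to
P(Bin(5, 0.78) ≥ 3)² ≈ 0.857 — somewhat above the 81/100 a human cohort
produced, since humans are not iid coin flips; the shipped analysis seed
happens to retain 81. Because the survey forced completion, missing
no-brainer answers are an error by default (`strict=True`); lenient mode
excludes such respondents instead. Overall no-brainer correctness is
reported both over all initial respondents and over the retained subset,
since either denominator is defensible.

## Inference (`inference`)

**Per-couple posterior.** Safer-choice counts k of n are binomial in p_i.
The estimator starts from the Jeffreys prior Beta(½, ½), performs a batch
update with a seeded-random 80% of the Bernoulli observations, then adds the
remaining 20% one at a time. Which observations form the first batch is
irrelevant by conjugacy — the final posterior is Beta(½+k, ½+n−k) for any
split and order, asserted exactly over an exhaustive (k, n) sweep — so the
unspecified partition rule is made irrelevant by construction rather than
guessed. Posteriors are carried analytically as beta parameters; the
"iterative" stage is executed procedurally but never leaves the conjugate
family.

**Aggregation.** The setting-level probability is the unweighted mean of the
35 per-couple posterior means, with sd propagated assuming independence
across couples: sd_s = √(Σ sd_i²)/m. Independence is an approximation (the
couples share respondents); it is isolated in `aggregate` so a correlated
variant could replace it.

**Group comparison.** z = (p_timed − p_control)/√(sd_timed² + sd_control²),
one-sided upper-tail normal p (alternative: timed more risk-averse), no
small-sample correction. Near-normality of the per-couple posteriors, which
motivates the z statistic, is checked by Shapiro–Wilk and Jarque–Bera on
draws from the analytic posterior (default 500 draws). Note that with
several hundred draws these tests have power to flag the mild skew of even
a Beta(30.5, 10.5), so small p-values there signal test power, not a broken
posterior; the diagnostic is reported, not gated on.

**Response times.** Two-sided Mann–Whitney U on per-respondent cumulative
times via `scipy.stats.mannwhitneyu(method="auto")`: exact enumeration for
small tie-free samples (verified against brute-force permutation
enumeration at group sizes ≤ 5), tie-corrected normal approximation
otherwise.

**Standardized ranking.** Final capitals use one shared coin flip per couple
and a standardized order (additive block then multiplicative, by couple
index): chosen additive outcomes are summed onto the 1000 start capital,
then chosen factors are multiplied. Ties share the best (competition) rank.

## Pipeline and reproducibility (`io`, CLI, analysis/)

One top-level seed fans out to stage seeds (bets, responses, estimation,
coin flips) through `numpy.random.SeedSequence.spawn`, so each stage is
independently rerunnable and every derived seed is recorded in the run
manifest together with config snapshot, artifact SHA-256 digests, and
version. All CSVs are comma-separated, UTF-8, headered. Figures are optional
artifacts; no numeric output depends on plotting. The numbered scripts in
`analysis/` are thin narrative drivers over the same library calls the
tests exercise; problem sizes throughout (100 respondents, 200×500
trajectories, 10⁴-couple audits, 10³ replicate null experiments) are chosen
to make every Monte-Carlo tolerance in the suite a 2–4σ bound at
interactive runtimes.

## Known limitations

* The generator encodes homogeneous within-group behaviour; it cannot test
  robustness to respondent heterogeneity or attention drift.
* Aggregation assumes independent couple posteriors (shared-respondent
  correlation is ignored), which slightly understates sd_s.
* The printed 80-couple table of the original study is treated as a
  structural template; the seeded generator produces statistically
  equivalent couples, not the same numeric entries.
* Only 50/50 outcome probabilities are supported; `p_lo` is carried through
  the closed forms but the generator always emits 0.5.
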