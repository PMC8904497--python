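"""Bayesian estimation of safer-bet probabilities and group comparisons.

Per couple *i* the number of risk-averse choices among *n* respondents is
binomial with parameter ``p_i``. Estimation is a two-stage conjugate
procedure: starting from the Jeffreys prior Beta(1/2, 1/2), a random 80% of
the Bernoulli observations form a first batch update (an "informed prior"),
and the remaining 20% are then added one observation at a time. Conjugacy
makes the final posterior Beta(1/2 + k, 1/2 + n - k) regardless of the split
or order — the procedure is reproduced faithfully and the invariance is a
tested property rather than an assumption.

Setting-level estimates average the per-couple posterior means and propagate
their uncertainties assuming independence across couples
(``sd_s = sqrt(sum sd_i^2) / m``). Timed and control groups are compared per
setting with a one-sided z test (alternative: timed respondents are more
risk-averse); posterior near-normality — which justifies the z statistic —
is checked per couple by Shapiro-Wilk and Jarque-Bera on posterior draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .betgen import BetCouple
from .dynamics import Dynamic

__all__ = [
    "PosteriorEstimate",
    "SettingEstimate",
    "GroupComparison",
    "NormalityResult",
    "ResponseTimeTest",
    "fit_couple",
    "estimate_couples",
    "aggregate",
    "compare_groups",
    "check_normality",
    "response_time_test",
    "standardized_ranking",
    "DegenerateComparisonError",
]

JEFFREYS_A = 0.5
JEFFREYS_B = 0.5


class DegenerateComparisonError(ValueError):
    """Both setting estimates carry zero uncertainty; z is undefined."""


@dataclass(frozen=True)
class PosteriorEstimate:
    """Beta posterior of the safer-bet probability for one couple."""

    alpha: float
    beta_param: float
    n: int
    k: int
    couple_index: int | None = None
    group: str | None = None
    setting: Dynamic | None = None

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_param)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta_param
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central posterior credible interval."""
        tail = (1.0 - level) / 2.0
        dist = stats.beta(self.alpha, self.beta_param)
        return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


@dataclass(frozen=True)
class SettingEstimate:
    """Aggregated safer-bet probability for one group within one setting."""

    group: str
    setting: Dynamic
    p_s: float
    sd_s: float
    m_couples: int


@dataclass(frozen=True)
class NormalityResult:
    couple_index: int | None
    shapiro_stat: float
    shapiro_p: float
    jarque_bera_stat: float
    jarque_bera_p: float


@dataclass(frozen=True)
class GroupComparison:
    """One-sided z comparison of timed vs control within a setting."""

    setting: Dynamic
    estimate_timed: SettingEstimate
    estimate_control: SettingEstimate
    z: float
    p_one_sided: float
    normality: tuple[NormalityResult, ...] = ()


@dataclass(frozen=True)
class ResponseTimeTest:
    u_statistic: float
    p_value: float
    median_timed: float
    median_control: float


def fit_couple(
    k: int,
    n: int,
    split_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
    *,
    couple_index: int | None = None,
    group: str | None = None,
    setting: Dynamic | None = None,
) -> PosteriorEstimate:
    """Two-stage Jeffreys-prior update from k successes in n Bernoulli trials.

    Stage 1 updates Beta(1/2, 1/2) with a random ``split_fraction`` subset of
    the observations in one batch; stage 2 adds the remaining observations
    one at a time. By conjugacy the result is Beta(1/2 + k, 1/2 + n - k)
    independent of the partition; the random split therefore only exercises
    the procedure. ``n = 0`` returns the bare Jeffreys prior with a warning.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= split_fraction <= 1.0):
        raise ValueError("split_fraction must lie in [0, 1]")
    meta = dict(couple_index=couple_index, group=group, setting=setting)
    if n == 0:
        warnings.warn("fit_couple called with n=0; returning the Jeffreys prior")
        return PosteriorEstimate(alpha=JEFFREYS_A, beta_param=JEFFREYS_B, n=0, k=0, **meta)

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = np.zeros(n, dtype=np.int64)
    obs[:k] = 1
    rng.shuffle(obs)

    n_prior = int(round(split_fraction * n))
    alpha = JEFFREYS_A + int(obs[:n_prior].sum())
    beta = JEFFREYS_B + n_prior - int(obs[:n_prior].sum())
    for x in obs[n_prior:]:  # iterative stage-2 updates, one observation each
        alpha += int(x)
        beta += 1 - int(x)
    return PosteriorEstimate(alpha=float(alpha), beta_param=float(beta), n=n, k=k, **meta)


def estimate_couples(
    responses: pd.DataFrame,
    split_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> list[PosteriorEstimate]:
    """Fit one posterior per (group, setting, couple) from scored responses.

    No-brainer rows (``chose_safer`` missing) are ignored.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scored = responses[responses["chose_safer"].notna()]
    grouped = scored.groupby(["group", "setting", "couple_index"], sort=True)["chose_safer"]
    estimates = []
    for (group, setting, idx), values in grouped:
        estimates.append(
            fit_couple(
                k=int(values.sum()),
                n=int(values.count()),
                split_fraction=split_fraction,
                rng=rng,
                couple_index=int(idx),
                group=str(group),
                setting=Dynamic(setting),
            )
        )
    return estimates


def aggregate(estimates: list[PosteriorEstimate]) -> SettingEstimate:
    """Setting-level estimate: unweighted mean of per-couple posterior means,
    uncertainty propagated under independence (sd_s = sqrt(Σ sd_i²)/m)."""
    if not estimates:
        raise ValueError("need at least one estimate")
    groups = {e.group for e in estimates}
    settings = {e.setting for e in estimates}
    if len(groups) != 1 or len(settings) != 1:
        raise ValueError("estimates mix groups or settings")
    m = len(estimates)
    p_s = sum(e.mean for e in estimates) / m
    sd_s = math.sqrt(sum(e.sd**2 for e in estimates)) / m
    return SettingEstimate(
        group=groups.pop(), setting=settings.pop(), p_s=p_s, sd_s=sd_s, m_couples=m
    )


def compare_groups(
    timed: SettingEstimate,
    control: SettingEstimate,
    normality: tuple[NormalityResult, ...] = (),
) -> GroupComparison:
    """One-sided z test of H1: p_timed > p_control within one setting."""
    if timed.setting != control.setting:
        raise ValueError("estimates come from different settings")
    pooled = math.sqrt(timed.sd_s**2 + control.sd_s**2)
    if pooled == 0.0:
        raise DegenerateComparisonError("zero pooled standard deviation")
    z = (timed.p_s - control.p_s) / pooled
    p = float(stats.norm.sf(z))
    return GroupComparison(
        setting=timed.setting,
        estimate_timed=timed,
        estimate_control=control,
        z=z,
        p_one_sided=p,
        normality=tuple(normality),
    )


def check_normality(
    estimate: PosteriorEstimate,
    n_draws: int = 500,
    rng: np.random.Generator | int | None = None,
) -> NormalityResult:
    """Shapiro-Wilk and Jarque-Bera on draws from the beta posterior."""
    if n_draws < 20:
        raise ValueError("n_draws must be >= 20")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = rng.beta(estimate.alpha, estimate.beta_param, size=n_draws)
    sw = stats.shapiro(draws)
    jb = stats.jarque_bera(draws)
    return NormalityResult(
        couple_index=estimate.couple_index,
        shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        jarque_bera_stat=float(jb.statistic),
        jarque_bera_p=float(jb.pvalue),
    )


def response_time_test(
    timed_totals, control_totals, method: str = "auto"
) -> ResponseTimeTest:
    """Two-sided Mann-Whitney U on cumulative response times.

    ``method="auto"`` uses the exact null distribution for small tie-free
    samples (agreeing with brute-force permutation enumeration) and the
    tie-corrected normal approximation otherwise.
    """
    timed = np.asarray(timed_totals, dtype=float)
    control = np.asarray(control_totals, dtype=float)
    if timed.size < 2 or control.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.mannwhitneyu(timed, control, alternative="two-sided", method=method)
    return ResponseTimeTest(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_timed=float(np.median(timed)),
        median_control=float(np.median(control)),
    )


def standardized_ranking(
    responses: pd.DataFrame,
    couples: list[BetCouple],
    coinflip_seed: int,
    start_capital: float = 1000.0,
) -> pd.DataFrame:
    """Final capitals under one shared set of coin flips and a standardized
    bet order (additive block first, couples in index order within a block).

    Every respondent's chosen bets are resolved with the same per-couple
    outcome draw; additive outcomes are summed onto the starting capital,
    then multiplicative factors are applied. Returns a table sorted by
    capital (descending) with competition ranks (ties share the best rank).
    """
    by_index = {c.index: c for c in couples}
    rng = np.random.default_rng(coinflip_seed)
    order = sorted(
        by_index.values(),
        key=lambda c: (0 if c.setting is Dynamic.ADDITIVE else 1, c.index),
    )
    flips = {c.index: ("lo" if rng.random() < 0.5 else "hi") for c in order}

    chosen = responses.set_index(["respondent_id", "couple_index"])
    capitals = {}
    for resp_id, sub in responses.groupby("respondent_id", sort=True):
        capital = float(start_capital)
        answered = set(sub["couple_index"])
        missing = [c.index for c in order if c.index not in answered]
        if missing:
            raise ValueError(f"respondent {resp_id} is missing choices for couples {missing}")
        for couple in order:
            row = chosen.loc[(resp_id, couple.index)]
            if couple.is_no_brainer:
                took_safer_slot = bool(row["nobrainer_correct"])
            else:
                took_safer_slot = int(row["chose_safer"]) == 1
            bet = couple.safer if took_safer_slot else couple.riskier
            outcome = bet.outcome_lo if flips[couple.index] == "lo" else bet.outcome_hi
            if couple.setting is Dynamic.ADDITIVE:
                capital += outcome
            else:
                capital *= outcome
        capitals[resp_id] = capital

    groups = responses.drop_duplicates("respondent_id").set_index("respondent_id")["group"]
    table = pd.DataFrame(
        {
            "respondent_id": list(capitals),
            "group": [groups.get(r) for r in capitals],
            "final_capital": list(capitals.values()),
        }
    ).sort_values("final_capital", ascending=False, kind="mergesort")
    table["rank"] = (
        table["final_capital"].rank(method="min", ascending=False).astype(int)
    )
    return table.reset_index(drop=True)
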