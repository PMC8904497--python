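"""Generation of equal-expected-value bet couples with unequal variance.

A *bet couple* pairs a riskier and a safer 50/50 bet with identical expected
value, so that choosing the lower-variance bet is unambiguously a risk-averse
decision (coded 1) and choosing the higher-variance bet a risk-taking one
(coded 0). The sampler draws the riskier bet uniformly from a bounded
parameter region, then places the safer bet on the equal-expected-value locus
at a strictly smaller spread. Outcomes are quantized — integers in the
additive setting, two decimals in the multiplicative setting — and expected
value equality is restored exactly on the quantized grid.

Dominated "no-brainer" couples, where one bet is state-wise at least as good
in every outcome and strictly better in at least one, are generated as
attention checks; they have an objectively correct answer and never enter the
risk-preference estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np

from .dynamics import Bet, Dynamic, time_avg_growth

__all__ = [
    "BetCouple",
    "ParameterSpace",
    "RiskCode",
    "bet_variance",
    "sample_couple",
    "make_no_brainer",
    "classify_choice",
    "check_lemma",
    "generate_bet_table",
    "ev_equal_on_grid",
    "NotClassifiableError",
    "GenerationError",
]

# scored couples per setting, then attention checks, mirroring the 80-couple
# layout: additive 1-35 scored / 36-40 no-brainer, multiplicative 41-75 / 76-80
N_SCORED = 35
N_NOBRAINER = 5

_MAX_SAMPLE_ATTEMPTS = 10_000


class GenerationError(RuntimeError):
    """The parameter space admits no couple (or sampling failed repeatedly)."""


class NotClassifiableError(ValueError):
    """Raised when a no-brainer couple is sent to risk classification."""


class RiskCode(IntEnum):
    """Binary coding of a choice: higher-variance bet = risk taking (0),
    lower-variance bet = risk averse (1)."""

    RISK_TAKING = 0
    RISK_AVERSE = 1


@dataclass(frozen=True)
class ParameterSpace:
    """Feasible region for generated bets.

    Additive setting: each outcome within ``±max_abs_outcome`` (default 300)
    and the expected value within ``±max_abs_ev`` (default 100).

    Multiplicative setting: each growth factor within
    ``[min_factor, max_factor]`` (default [0.7, 1.4]) and the riskier bet's
    time-average growth factor ``sqrt(lo*hi)`` within
    ``[min_growth, max_growth]`` (default [0.945, 1.05]).
    """

    setting: Dynamic
    max_abs_outcome: float = 300.0
    max_abs_ev: float = 100.0
    min_factor: float = 0.7
    max_factor: float = 1.4
    min_growth: float = 0.945
    max_growth: float = 1.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "setting", Dynamic(self.setting))
        if self.setting is Dynamic.ADDITIVE:
            if not (0 < self.max_abs_ev <= self.max_abs_outcome):
                raise GenerationError("additive bounds must satisfy 0 < EV bound <= outcome bound")
        else:
            if not (0 < self.min_factor < self.max_factor):
                raise GenerationError("factor bounds must be positive and ordered")
            if not (self.min_growth < self.max_growth):
                raise GenerationError("growth bounds must be ordered")


@dataclass(frozen=True)
class BetCouple:
    """A riskier/safer pair of equal-expected-value bets.

    For no-brainer couples the ``safer`` slot holds the state-wise dominant
    bet (the objectively correct answer) and the riskier/safer labels carry
    no variance meaning.
    """

    index: int
    setting: Dynamic
    riskier: Bet
    safer: Bet
    is_no_brainer: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "setting", Dynamic(self.setting))

    @property
    def quantum(self) -> float:
        """Grid step of the quantized outcomes for this setting."""
        return 1.0 if self.setting is Dynamic.ADDITIVE else 0.01


def bet_variance(bet: Bet) -> float:
    """Population variance of the two-point outcome distribution:
    ``p(1-p)(hi-lo)^2``."""
    return bet.p_lo * (1.0 - bet.p_lo) * bet.spread**2


def _to_grid(x: float, quantum: float) -> int:
    return int(round(x / quantum))


def ev_equal_on_grid(couple: BetCouple) -> bool:
    """Exact expected-value equality on the setting's quantized grid."""
    q = couple.quantum
    r = _to_grid(couple.riskier.outcome_lo, q) + _to_grid(couple.riskier.outcome_hi, q)
    s = _to_grid(couple.safer.outcome_lo, q) + _to_grid(couple.safer.outcome_hi, q)
    return r == s


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def _safer_spread_choices(total: int, spread: int) -> np.ndarray:
    """Admissible quantized spreads for the safer bet: same parity as the
    outcome sum (so both outcomes stay on-grid), strictly smaller than the
    riskier spread, non-negative."""
    parity = total & 1
    start = parity  # smallest non-negative integer with the right parity
    return np.arange(start, spread, 2)


def _sample_riskier_additive(space: ParameterSpace, rng: np.random.Generator):
    """Uniform point of the additive feasible region, quantized to integers."""
    bound = space.max_abs_outcome
    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        a, b = rng.uniform(-bound, bound, size=2)
        lo, hi = (a, b) if a <= b else (b, a)
        if abs(lo + hi) / 2.0 > space.max_abs_ev:
            continue
        lo_g, hi_g = int(round(lo)), int(round(hi))
        if hi_g <= lo_g:
            continue
        if abs(lo_g + hi_g) / 2.0 > space.max_abs_ev or max(abs(lo_g), abs(hi_g)) > bound:
            continue
        return lo_g, hi_g
    raise GenerationError("could not sample an additive riskier bet")


def _sample_riskier_multiplicative(space: ParameterSpace, rng: np.random.Generator):
    """Uniform point of the multiplicative region (factor box intersected
    with the growth-factor band), quantized to hundredths."""
    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        a, b = rng.uniform(space.min_factor, space.max_factor, size=2)
        lo, hi = (a, b) if a <= b else (b, a)
        if not (space.min_growth <= math.sqrt(lo * hi) <= space.max_growth):
            continue
        lo_g, hi_g = int(round(lo * 100)), int(round(hi * 100))
        if hi_g <= lo_g:
            continue
        if lo_g < round(space.min_factor * 100) or hi_g > round(space.max_factor * 100):
            continue
        if not (space.min_growth <= math.sqrt(lo_g * hi_g) / 100.0 <= space.max_growth):
            continue
        return lo_g, hi_g
    raise GenerationError("could not sample a multiplicative riskier bet")


def sample_couple(space: ParameterSpace, rng_seed) -> BetCouple:
    """Draw one scored bet couple from the parameter space.

    The riskier bet is sampled uniformly over the feasible region; the safer
    bet shares its (quantized) expected value with a spread drawn uniformly
    from the strictly smaller on-grid spreads. Couples whose quantization
    leaves no strictly smaller spread are rejected and resampled.
    """
    rng = _as_rng(rng_seed)
    additive = space.setting is Dynamic.ADDITIVE
    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        if additive:
            lo_g, hi_g = _sample_riskier_additive(space, rng)
        else:
            lo_g, hi_g = _sample_riskier_multiplicative(space, rng)
        total, spread = lo_g + hi_g, hi_g - lo_g
        choices = _safer_spread_choices(total, spread)
        if choices.size == 0:
            continue
        d = int(rng.choice(choices))
        s_lo, s_hi = (total - d) // 2, (total + d) // 2
        q = 1.0 if additive else 0.01
        riskier = Bet(round(lo_g * q, 2), round(hi_g * q, 2))
        safer = Bet(round(s_lo * q, 2), round(s_hi * q, 2))
        return BetCouple(index=0, setting=space.setting, riskier=riskier, safer=safer)
    raise GenerationError("could not sample a couple from the given space")


def make_no_brainer(space: ParameterSpace, rng_seed) -> BetCouple:
    """Draw a dominated couple: the dominant bet's outcomes are state-wise at
    least as good, at least one strictly better. The dominant bet sits in the
    ``safer`` slot as the correct answer."""
    rng = _as_rng(rng_seed)
    additive = space.setting is Dynamic.ADDITIVE
    upper = int(round(space.max_abs_outcome if additive else space.max_factor * 100))
    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        if additive:
            lo_g, hi_g = _sample_riskier_additive(space, rng)
        else:
            lo_g, hi_g = _sample_riskier_multiplicative(space, rng)
        room_lo, room_hi = upper - lo_g, upper - hi_g
        if room_lo <= 0 and room_hi <= 0:
            continue
        d_lo = int(rng.integers(0, room_lo + 1)) if room_lo > 0 else 0
        d_hi = int(rng.integers(0, room_hi + 1)) if room_hi > 0 else 0
        if d_lo == 0 and d_hi == 0:
            continue
        dom_lo, dom_hi = lo_g + d_lo, hi_g + d_hi
        if dom_hi < dom_lo:  # keep outcomes ordered within the dominant bet
            continue
        if additive and abs(dom_lo + dom_hi) / 2.0 > space.max_abs_ev:
            continue
        q = 1.0 if additive else 0.01
        dominated = Bet(round(lo_g * q, 2), round(hi_g * q, 2))
        dominant = Bet(round(dom_lo * q, 2), round(dom_hi * q, 2))
        return BetCouple(
            index=0,
            setting=space.setting,
            riskier=dominated,
            safer=dominant,
            is_no_brainer=True,
        )
    raise GenerationError("could not generate a no-brainer couple")


def generate_bet_table(
    seed: int,
    n_scored: int = N_SCORED,
    n_nobrainer: int = N_NOBRAINER,
    spaces: Sequence[ParameterSpace] | None = None,
) -> list[BetCouple]:
    """Generate the full experiment table: scored couples then no-brainers
    for the additive setting, then the same for the multiplicative setting,
    consecutively indexed from 1."""
    rng = np.random.default_rng(seed)
    if spaces is None:
        spaces = (
            ParameterSpace(Dynamic.ADDITIVE),
            ParameterSpace(Dynamic.MULTIPLICATIVE),
        )
    couples: list[BetCouple] = []
    idx = 1
    for space in spaces:
        for _ in range(n_scored):
            couples.append(replace(sample_couple(space, rng), index=idx))
            idx += 1
        for _ in range(n_nobrainer):
            couples.append(replace(make_no_brainer(space, rng), index=idx))
            idx += 1
    return couples


def classify_choice(couple: BetCouple, chosen) -> RiskCode:
    """Code a choice: safer bet -> risk averse (1), riskier -> risk taking (0).

    ``chosen`` is either the literal slot name (``"safer"``/``"riskier"``) or
    one of the couple's :class:`Bet` objects. No-brainer couples are not
    classifiable (they have a correct answer, not a risk preference).
    """
    if couple.is_no_brainer:
        raise NotClassifiableError(
            f"couple {couple.index} is a no-brainer; route it to QC instead"
        )
    if chosen == "safer" or chosen == couple.safer:
        return RiskCode.RISK_AVERSE
    if chosen == "riskier" or chosen == couple.riskier:
        return RiskCode.RISK_TAKING
    raise ValueError(f"{chosen!r} is not a bet of couple {couple.index}")


def check_lemma(couple: BetCouple, utility: Callable[[float], float]) -> bool:
    """Whether the safer bet is weakly preferred under ``utility``.

    For an equal-expected-value couple with outcomes ordered
    ``a < b <= c < d`` (riskier outer, safer inner), Jensen's inequality
    forces every monotone utility with concave curvature to weakly prefer the
    safer bet, every convex one the riskier bet, and a linear utility to be
    exactly indifferent.
    """
    a, d = couple.riskier.outcome_lo, couple.riskier.outcome_hi
    b, c = couple.safer.outcome_lo, couple.safer.outcome_hi
    if not (a <= b <= c <= d):
        raise ValueError("safer outcomes must lie inside the riskier outcomes")
    p, q = couple.safer.p_lo, couple.riskier.p_lo
    try:
        eu_safer = p * utility(b) + (1 - p) * utility(c)
        eu_riskier = q * utility(a) + (1 - q) * utility(d)
    except (ValueError, ZeroDivisionError, OverflowError) as exc:
        raise ValueError(f"utility not defined on [{a}, {d}]") from exc
    scale = max(abs(eu_safer), abs(eu_riskier), 1.0)
    return eu_safer >= eu_riskier - 1e-10 * scale
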