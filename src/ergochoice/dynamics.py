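"""Additive and multiplicative wealth dynamics for repeated two-outcome gambles.

A bet is a 50/50 (configurable) gamble between two outcomes. In the additive
dynamic the drawn outcome is added to capital; in the multiplicative dynamic
capital is multiplied by the drawn growth factor. The two dynamics differ in
ergodicity: for additive dynamics the expected per-round increment (ensemble
average) equals the per-round increment experienced by a single long-lived
player (time average), while for multiplicative dynamics the expected growth
factor can exceed 1 while the time-average growth rate is negative — the
classic example being the gamble that multiplies capital by 1.5 or 0.6 with
equal probability (+5% expected gain per round, yet ln(0.9)/2 ≈ -5.3% per
round along any single trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Bet",
    "Dynamic",
    "TrajectoryEnsemble",
    "ensemble_ev",
    "time_avg_growth",
    "simulate_trajectories",
    "ergodic_transform",
    "InvalidBetError",
]


class InvalidBetError(ValueError):
    """A bet violates the requirements of the dynamic it is used under."""


class Dynamic(str, Enum):
    """Wealth-accumulation mode: outcomes add to, or multiply, capital."""

    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class Bet:
    """A two-outcome gamble.

    Parameters
    ----------
    outcome_lo, outcome_hi
        The two possible outcomes, ordered ``outcome_lo <= outcome_hi``.
        Currency increments in the additive dynamic, growth factors in the
        multiplicative dynamic.
    p_lo
        Probability of the low outcome. All bets in this study use 0.5.
    """

    outcome_lo: float
    outcome_hi: float
    p_lo: float = 0.5

    def __post_init__(self) -> None:
        if not (self.outcome_lo <= self.outcome_hi):
            raise InvalidBetError(
                f"outcome_lo ({self.outcome_lo}) must not exceed "
                f"outcome_hi ({self.outcome_hi})"
            )
        if not (0.0 < self.p_lo < 1.0):
            raise InvalidBetError(f"p_lo must lie in (0, 1), got {self.p_lo}")

    @property
    def spread(self) -> float:
        return self.outcome_hi - self.outcome_lo


def _validate(bet: Bet, dynamic: Dynamic) -> None:
    if dynamic is Dynamic.MULTIPLICATIVE and bet.outcome_lo <= 0:
        raise InvalidBetError(
            "multiplicative bets require strictly positive growth factors, "
            f"got outcomes ({bet.outcome_lo}, {bet.outcome_hi})"
        )


def ensemble_ev(bet: Bet, dynamic: Dynamic) -> float:
    """Ensemble average of one round: expected increment (additive) or
    expected growth factor (multiplicative)."""
    dynamic = Dynamic(dynamic)
    _validate(bet, dynamic)
    return bet.p_lo * bet.outcome_lo + (1.0 - bet.p_lo) * bet.outcome_hi


def time_avg_growth(bet: Bet, dynamic: Dynamic) -> float:
    """Per-round growth experienced by a single player as rounds → ∞.

    Additive dynamics are ergodic, so this coincides with
    :func:`ensemble_ev`. For multiplicative dynamics it is the expected log
    growth factor ``p·ln lo + (1−p)·ln hi`` (``½·ln(lo·hi)`` at 50/50),
    which by AM–GM never exceeds ``ln(ensemble_ev)``.
    """
    dynamic = Dynamic(dynamic)
    _validate(bet, dynamic)
    if dynamic is Dynamic.ADDITIVE:
        return ensemble_ev(bet, dynamic)
    return bet.p_lo * math.log(bet.outcome_lo) + (1.0 - bet.p_lo) * math.log(
        bet.outcome_hi
    )


def ergodic_transform(value: float, dynamic: Dynamic) -> float:
    """Map capital to the scale on which increments are ergodic.

    Identity for the additive dynamic; natural log for the multiplicative
    dynamic.
    """
    dynamic = Dynamic(dynamic)
    if dynamic is Dynamic.ADDITIVE:
        return float(value)
    if value <= 0:
        raise InvalidBetError(
            f"ergodic transform of the multiplicative dynamic requires a "
            f"positive argument, got {value}"
        )
    return math.log(value)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Capital paths of ``n_individuals`` playing the same bet repeatedly.

    ``capital`` has shape ``(n_individuals, n_rounds + 1)``; column 0 is the
    common starting capital.
    """

    capital: np.ndarray
    start_capital: float
    dynamic: Dynamic
    bet: Bet
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.capital.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.capital.shape[1] - 1

    def ensemble_mean(self) -> np.ndarray:
        """Mean capital across individuals, one value per round."""
        return self.capital.mean(axis=0)

    def ensemble_median(self) -> np.ndarray:
        return np.median(self.capital, axis=0)

    def growth_increments(self) -> np.ndarray:
        """Per-round increments on the ergodic scale.

        Additive: differences of capital. Multiplicative: differences of log
        capital. Shape ``(n_individuals, n_rounds)``; their grand mean is the
        natural estimator of :func:`time_avg_growth`.
        """
        if self.dynamic is Dynamic.ADDITIVE:
            return np.diff(self.capital, axis=1)
        return np.diff(np.log(self.capital), axis=1)

    def to_long_frame(self):
        """Long-format table (individual, round, capital)."""
        import pandas as pd

        n_ind, n_col = self.capital.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n_ind), n_col),
                "round": np.tile(np.arange(n_col), n_ind),
                "capital": self.capital.ravel(),
            }
        )


def simulate_trajectories(
    bet: Bet,
    dynamic: Dynamic,
    n_individuals: int,
    n_rounds: int,
    start_capital: float = 1000.0,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Simulate independent capital trajectories under one repeated bet.

    Each round every individual independently draws the low outcome with
    probability ``p_lo``, otherwise the high outcome. Draws are consumed
    round-major: one seeded generator supplies a full cross-section of
    individuals per round, so the matrix is reproducible from ``seed``.
    """
    dynamic = Dynamic(dynamic)
    _validate(bet, dynamic)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    if start_capital <= 0:
        raise ValueError("start_capital must be positive")

    rng = np.random.default_rng(seed)
    # round-major draw order: shape (n_rounds, n_individuals)
    lo_mask = rng.random((n_rounds, n_individuals)) < bet.p_lo
    outcomes = np.where(lo_mask, bet.outcome_lo, bet.outcome_hi)

    capital = np.empty((n_individuals, n_rounds + 1), dtype=float)
    capital[:, 0] = start_capital
    if n_rounds:
        if dynamic is Dynamic.ADDITIVE:
            capital[:, 1:] = start_capital + np.cumsum(outcomes.T, axis=1)
        else:
            capital[:, 1:] = start_capital * np.cumprod(outcomes.T, axis=1)
    return TrajectoryEnsemble(
        capital=capital,
        start_capital=float(start_capital),
        dynamic=dynamic,
        bet=bet,
        seed=int(seed),
    )
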