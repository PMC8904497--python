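"""Synthetic respondents for the stated-choice experiment.

The deposited human data cannot ship with the package, so this module
generates respondent-choice tables with the same statistical structure: ~100
respondents split into a timed and a control group, each answering 80 bet
couples (35 scored + 5 no-brainer attention checks per setting), with
per-couple response times whose cumulative group medians match configured
targets.

Agents score each bet with a decision model and choose stochastically via a
logistic (softmax) rule over the two scores. The default scenario encodes
the behavioural hypothesis under study: timed respondents act like
time-average-growth optimizers (with moderate choice noise), control
respondents are indifferent between equal-expected-value bets. Under
equal-EV couples this yields a safer-bet preference for the timed group in
the multiplicative setting only — the pattern the inference stage is meant
to detect — and exactly 0.5 for every ev-indifferent agent by symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .betgen import BetCouple, RiskCode
from .dynamics import Bet, Dynamic, ensemble_ev, time_avg_growth

__all__ = [
    "AgentModel",
    "AgentSpec",
    "ExperimentConfig",
    "decision_value",
    "choice_probability",
    "choose",
    "generate_dataset",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = [
    "respondent_id",
    "group",
    "setting",
    "couple_index",
    "chose_safer",
    "nobrainer_correct",
    "response_time_s",
    "presentation_order",
]


class AgentModel(str, Enum):
    EV_INDIFFERENT = "ev_indifferent"
    TIME_AVERAGE_OPTIMIZER = "time_average_optimizer"
    ISOELASTIC = "isoelastic"


@dataclass(frozen=True)
class AgentSpec:
    """Decision model plus noise parameters for one agent population.

    ``choice_temperature`` scales the logistic choice rule (smaller = more
    deterministic); ``nobrainer_error_rate`` is the per-answer probability of
    missing a dominated attention-check couple; ``eta`` is the coefficient of
    relative risk aversion, used only by the isoelastic model.
    """

    model: AgentModel = AgentModel.EV_INDIFFERENT
    eta: float | None = None
    choice_temperature: float = 0.02
    nobrainer_error_rate: float = 0.22

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", AgentModel(self.model))
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be positive")
        if not (0.0 <= self.nobrainer_error_rate < 0.5):
            raise ValueError("nobrainer_error_rate must lie in [0, 0.5)")
        if self.model is AgentModel.ISOELASTIC and self.eta is None:
            raise ValueError("isoelastic model requires eta")


def _isoelastic_u(x: float, eta: float) -> float:
    if x <= 0:
        raise ValueError(f"isoelastic utility requires positive wealth, got {x}")
    if eta == 1.0:
        return math.log(x)
    return (x ** (1.0 - eta) - 1.0) / (1.0 - eta)


def decision_value(
    agent: AgentSpec, bet: Bet, setting: Dynamic, reference_wealth: float = 1000.0
) -> float:
    """Score a bet under the agent's decision model.

    ev_indifferent scores by the ensemble average, time_average_optimizer by
    the time-average growth rate, isoelastic by the expected utility of
    end-of-round wealth starting from ``reference_wealth`` (respondents get
    no capital feedback during the task, so the reference stays fixed).
    """
    setting = Dynamic(setting)
    if agent.model is AgentModel.EV_INDIFFERENT:
        return ensemble_ev(bet, setting)
    if agent.model is AgentModel.TIME_AVERAGE_OPTIMIZER:
        return time_avg_growth(bet, setting)
    # isoelastic expected utility of one round from the reference wealth
    if setting is Dynamic.ADDITIVE:
        wealths = (reference_wealth + bet.outcome_lo, reference_wealth + bet.outcome_hi)
    else:
        wealths = (reference_wealth * bet.outcome_lo, reference_wealth * bet.outcome_hi)
    p = bet.p_lo
    return p * _isoelastic_u(wealths[0], agent.eta) + (1 - p) * _isoelastic_u(
        wealths[1], agent.eta
    )


def choice_probability(
    agent: AgentSpec, couple: BetCouple, setting: Dynamic | None = None
) -> float:
    """Closed-form probability that the agent picks the safer bet of a scored
    couple under the logistic choice rule."""
    setting = Dynamic(setting if setting is not None else couple.setting)
    v_s = decision_value(agent, couple.safer, setting)
    v_r = decision_value(agent, couple.riskier, setting)
    z = (v_s - v_r) / agent.choice_temperature
    return 1.0 / (1.0 + math.exp(-z)) if z > -700 else 0.0


def choose(
    agent: AgentSpec,
    couple: BetCouple,
    setting: Dynamic,
    rng: np.random.Generator,
) -> str:
    """Stochastic choice: returns ``"safer"`` or ``"riskier"`` (slot names).

    Scored couples follow the logistic rule over decision values; no-brainer
    couples are answered correctly (dominant bet, held in the safer slot)
    with probability ``1 - nobrainer_error_rate``.
    """
    if couple.is_no_brainer:
        correct = rng.random() >= agent.nobrainer_error_rate
        return "safer" if correct else "riskier"
    p_safer = choice_probability(agent, couple, setting)
    return "safer" if rng.random() < p_safer else "riskier"


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the study: 100 respondents split roughly evenly into
    timed and control groups, a starting capital of 1000, cumulative
    response-time medians of 579 s (timed) and 694 s (control), with the
    control group more dispersed.
    """

    n_respondents: int = 100
    p_timed: float = 0.5
    seed: int = 0
    timed_agent: AgentSpec = field(
        default_factory=lambda: AgentSpec(model=AgentModel.TIME_AVERAGE_OPTIMIZER)
    )
    control_agent: AgentSpec = field(
        default_factory=lambda: AgentSpec(model=AgentModel.EV_INDIFFERENT)
    )
    median_time_timed_s: float = 579.0
    median_time_control_s: float = 694.0
    time_sigma_timed: float = 0.25
    time_sigma_control: float = 0.45
    starting_capital: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_respondents < 4:
            raise ValueError("need at least 2 respondents per group")
        if not (0.0 < self.p_timed < 1.0):
            raise ValueError("p_timed must lie in (0, 1)")
        if self.starting_capital <= 0:
            raise ValueError("starting_capital must be positive")


def generate_dataset(
    config: ExperimentConfig, couples: list[BetCouple]
) -> pd.DataFrame:
    """Simulate every respondent answering all couples.

    The two settings are played as independent blocks in a random order;
    couple order within a block and the within-couple presentation order are
    randomized per respondent. Each respondent's cumulative response time is
    log-normal with the group's target median; per-couple times split the
    total via a Dirichlet draw, so group medians of cumulative time converge
    to the configured targets. Fully reproducible from ``config.seed``.
    """
    if not couples:
        raise ValueError("bet table is empty")
    rng = np.random.default_rng(config.seed)
    by_setting: dict[Dynamic, list[BetCouple]] = {}
    for c in couples:
        by_setting.setdefault(c.setting, []).append(c)

    rows: list[dict] = []
    for resp in range(config.n_respondents):
        resp_id = f"R{resp:03d}"
        timed = rng.random() < config.p_timed
        group = "timed" if timed else "control"
        agent = config.timed_agent if timed else config.control_agent
        median = config.median_time_timed_s if timed else config.median_time_control_s
        sigma = config.time_sigma_timed if timed else config.time_sigma_control

        settings = list(by_setting)
        rng.shuffle(settings)
        ordered: list[BetCouple] = []
        for setting in settings:
            block = list(by_setting[setting])
            rng.shuffle(block)
            ordered.extend(block)

        total_time = float(rng.lognormal(mean=math.log(median), sigma=sigma))
        fractions = rng.dirichlet(np.full(len(ordered), 8.0))
        times = total_time * fractions

        for couple, t in zip(ordered, times):
            slot = choose(agent, couple, couple.setting, rng)
            order = "safer_first" if rng.random() < 0.5 else "riskier_first"
            row = {
                "respondent_id": resp_id,
                "group": group,
                "setting": couple.setting.value,
                "couple_index": couple.index,
                "chose_safer": pd.NA,
                "nobrainer_correct": pd.NA,
                "response_time_s": float(t),
                "presentation_order": order,
            }
            if couple.is_no_brainer:
                row["nobrainer_correct"] = slot == "safer"
            else:
                row["chose_safer"] = int(RiskCode.RISK_AVERSE if slot == "safer" else RiskCode.RISK_TAKING)
            rows.append(row)

    frame = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    frame["chose_safer"] = frame["chose_safer"].astype("Int64")
    frame["nobrainer_correct"] = frame["nobrainer_correct"].astype("boolean")
    return frame
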