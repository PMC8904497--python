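"""Quality control: the no-brainer attention filter and response-time summaries.

Each setting contains five dominated "no-brainer" couples with an
objectively correct answer. A respondent is retained for analysis only if
they answered at least 3 of 5 correctly in *each* setting — the requirement
is a per-setting conjunction, so acing one block cannot compensate for
failing the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["QCReport", "apply_filter", "summarize_times", "cumulative_times", "MissingAnswersError"]

NOBRAINERS_PER_SETTING = 5


class MissingAnswersError(ValueError):
    """A respondent lacks answers for some no-brainer couples (strict mode)."""


@dataclass(frozen=True)
class QCReport:
    """Summary of the attention filter.

    ``frac_correct_all`` is the fraction of correct no-brainer answers over
    every initial respondent; ``frac_correct_retained`` restricts the same
    fraction to the retained respondents (the study's headline "78% correct"
    figure is ambiguous between the two, so both are reported).
    """

    n_initial: int
    n_retained: int
    threshold: int
    per_respondent: pd.DataFrame  # respondent_id, group, per-setting correct counts, retained
    frac_correct_all: float
    frac_correct_retained: float


def apply_filter(
    responses: pd.DataFrame, threshold: int = 3, strict: bool = True
) -> tuple[pd.DataFrame, QCReport]:
    """Retain respondents with >= ``threshold`` correct no-brainers in every
    setting; return the retained response rows and a :class:`QCReport`.

    ``strict=True`` raises :class:`MissingAnswersError` when a respondent did
    not answer all no-brainer couples of every setting; ``strict=False``
    silently excludes such respondents instead.
    """
    nb = responses[responses["nobrainer_correct"].notna()].copy()
    nb["nobrainer_correct"] = nb["nobrainer_correct"].astype(bool)
    settings = sorted(responses["setting"].unique())

    counts = (
        nb.groupby(["respondent_id", "setting"], sort=True)["nobrainer_correct"]
        .agg(n_correct="sum", n_answered="count")
        .reset_index()
    )
    wide = counts.pivot(index="respondent_id", columns="setting")
    all_ids = pd.Index(sorted(responses["respondent_id"].unique()), name="respondent_id")
    n_correct = wide["n_correct"].reindex(all_ids).reindex(columns=settings)
    n_answered = wide["n_answered"].reindex(all_ids).reindex(columns=settings).fillna(0)

    complete = (n_answered == NOBRAINERS_PER_SETTING).all(axis=1)
    if strict and not complete.all():
        bad = list(all_ids[~complete])
        raise MissingAnswersError(
            f"respondents with missing no-brainer answers: {bad}"
        )
    passed = (n_correct.fillna(-1) >= threshold).all(axis=1) & complete

    groups = responses.drop_duplicates("respondent_id").set_index("respondent_id")["group"]
    per_respondent = pd.DataFrame(
        {
            "respondent_id": all_ids,
            "group": groups.reindex(all_ids).to_numpy(),
            "retained": passed.to_numpy(),
        }
    )
    for s in settings:
        per_respondent[f"n_correct_{s}"] = n_correct[s].fillna(0).astype(int).to_numpy()

    retained_ids = set(all_ids[passed])
    retained = responses[responses["respondent_id"].isin(retained_ids)].copy()

    nb_retained = nb[nb["respondent_id"].isin(retained_ids)]
    report = QCReport(
        n_initial=len(all_ids),
        n_retained=len(retained_ids),
        threshold=threshold,
        per_respondent=per_respondent,
        frac_correct_all=float(nb["nobrainer_correct"].mean()) if len(nb) else float("nan"),
        frac_correct_retained=(
            float(nb_retained["nobrainer_correct"].mean()) if len(nb_retained) else float("nan")
        ),
    )
    return retained, report


def cumulative_times(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-respondent cumulative response time (sum over all answers)."""
    totals = (
        responses.groupby(["respondent_id", "group"], sort=True)["response_time_s"]
        .sum()
        .reset_index()
        .rename(columns={"response_time_s": "total_time_s"})
    )
    return totals


def summarize_times(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-group median and quartiles of cumulative response time."""
    totals = cumulative_times(responses)
    summary = (
        totals.groupby("group")["total_time_s"]
        .agg(
            n="count",
            median="median",
            q1=lambda x: x.quantile(0.25),
            q3=lambda x: x.quantile(0.75),
        )
        .reset_index()
    )
    return summary
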