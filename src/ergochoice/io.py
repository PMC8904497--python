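"""CSV schemas, configuration loading, seed fan-out, and the end-to-end run.

Bet tables use the columns ``couple_index, setting, bet1_lo, bet1_hi,
bet2_lo, bet2_hi, safer_bet, is_no_brainer`` with bet 1 the riskier bet and
``safer_bet`` naming the slot (1 or 2) holding the safer — for no-brainers,
the dominant — bet. All CSVs are comma-separated, UTF-8, headered, with
locale-independent decimal points.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import (
    RESPONSE_COLUMNS,
    AgentSpec,
    ExperimentConfig,
    generate_dataset,
)
from .betgen import Bet, BetCouple, generate_bet_table
from .dynamics import Dynamic
from .inference import (
    aggregate,
    check_normality,
    compare_groups,
    estimate_couples,
    response_time_test,
    standardized_ranking,
)
from .qc import apply_filter, cumulative_times, summarize_times

__all__ = [
    "BET_TABLE_COLUMNS",
    "read_bet_table",
    "write_bet_table",
    "read_responses",
    "write_responses",
    "load_config",
    "stage_seeds",
    "RunManifest",
    "run_experiment",
    "BetTableError",
]

BET_TABLE_COLUMNS = [
    "couple_index",
    "setting",
    "bet1_lo",
    "bet1_hi",
    "bet2_lo",
    "bet2_hi",
    "safer_bet",
    "is_no_brainer",
]


class BetTableError(ValueError):
    """Malformed bet-table file."""


def write_bet_table(couples: list[BetCouple], path) -> None:
    rows = []
    for c in couples:
        rows.append(
            {
                "couple_index": c.index,
                "setting": c.setting.value,
                "bet1_lo": c.riskier.outcome_lo,
                "bet1_hi": c.riskier.outcome_hi,
                "bet2_lo": c.safer.outcome_lo,
                "bet2_hi": c.safer.outcome_hi,
                "safer_bet": 2,
                "is_no_brainer": c.is_no_brainer,
            }
        )
    pd.DataFrame(rows, columns=BET_TABLE_COLUMNS).to_csv(path, index=False)


def read_bet_table(path) -> list[BetCouple]:
    """Read and validate a bet-table CSV; errors name the offending row and
    column. Multiplicative outcomes outside [0.7, 1.4] raise a warning (the
    generator's default parameter-space bounds)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise BetTableError(f"{path}: empty bet-table file") from None
    if frame.empty:
        raise BetTableError(f"{path}: bet table has no rows")
    missing = [c for c in BET_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise BetTableError(f"{path}: missing columns {missing}")

    couples = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            setting = Dynamic(str(row["setting"]))
        except ValueError:
            raise BetTableError(f"{path}:{line}: column 'setting': {row['setting']!r}")
        try:
            b1 = Bet(float(row["bet1_lo"]), float(row["bet1_hi"]))
            b2 = Bet(float(row["bet2_lo"]), float(row["bet2_hi"]))
            safer_slot = int(row["safer_bet"])
            idx = int(row["couple_index"])
            nb = bool(row["is_no_brainer"])
        except (TypeError, ValueError) as exc:
            raise BetTableError(f"{path}:{line}: {exc}") from None
        if safer_slot not in (1, 2):
            raise BetTableError(f"{path}:{line}: column 'safer_bet' must be 1 or 2")
        if setting is Dynamic.MULTIPLICATIVE:
            outs = [b1.outcome_lo, b1.outcome_hi, b2.outcome_lo, b2.outcome_hi]
            if min(outs) < 0.7 or max(outs) > 1.4:
                warnings.warn(
                    f"{path}:{line}: multiplicative outcome outside the "
                    f"default [0.7, 1.4] bet parameter bounds"
                )
        safer, riskier = (b2, b1) if safer_slot == 2 else (b1, b2)
        couples.append(
            BetCouple(index=idx, setting=setting, riskier=riskier, safer=safer, is_no_brainer=nb)
        )
    return couples


def write_responses(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, index=False, columns=RESPONSE_COLUMNS)


def read_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing response columns {missing}")
    frame["chose_safer"] = frame["chose_safer"].astype("Int64")
    frame["nobrainer_correct"] = frame["nobrainer_correct"].astype("boolean")
    return frame


def load_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a flat YAML mapping.

    Agent fields are namespaced ``timed_agent_*`` / ``control_agent_*``;
    everything else maps directly onto config fields.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    agents: dict[str, dict] = {"timed_agent": {}, "control_agent": {}}
    for key, value in raw.items():
        matched = False
        for prefix in agents:
            if key.startswith(prefix + "_"):
                agents[prefix][key[len(prefix) + 1 :]] = value
                matched = True
        if not matched:
            kwargs[key] = value
    for prefix, fields in agents.items():
        if fields:
            kwargs[prefix] = AgentSpec(**fields)
    return ExperimentConfig(**kwargs)


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Fan one top-level seed out to independent per-stage seeds.

    Uses ``numpy.random.SeedSequence.spawn`` so the derivation is documented
    and stable; each stage can be rerun in isolation from its own seed.
    """
    children = np.random.SeedSequence(root_seed).spawn(4)
    names = ["bets", "responses", "estimation", "coinflips"]
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seeds: dict
    artifacts: dict  # filename -> sha256 digest
    version: str
    timestamp: str


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: ExperimentConfig) -> dict:
    snap = dataclasses.asdict(config)
    for key in ("timed_agent", "control_agent"):
        snap[key]["model"] = str(snap[key]["model"].value)
    return snap


def run_experiment(
    config: ExperimentConfig,
    out_dir,
    bet_seed: int | None = None,
    make_figures: bool = False,
) -> RunManifest:
    """Run the full pipeline: generate bets, synthesize respondents, apply
    the no-brainer filter, estimate per-couple posteriors, compare groups per
    setting, rank standardized final capitals, and write all artifacts plus
    a manifest to ``out_dir``. Deterministic given the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    if bet_seed is not None:
        seeds["bets"] = int(bet_seed)

    couples = generate_bet_table(seeds["bets"])
    write_bet_table(couples, out / "bet_table.csv")

    responses = generate_dataset(
        dataclasses.replace(config, seed=seeds["responses"]), couples
    )
    write_responses(responses, out / "responses.csv")

    retained, qc_report = apply_filter(responses)
    qc_report.per_respondent.to_csv(out / "qc_respondents.csv", index=False)
    summarize_times(retained).to_csv(out / "time_summary.csv", index=False)

    est_rng = np.random.default_rng(seeds["estimation"])
    estimates = estimate_couples(retained, rng=est_rng)
    est_frame = pd.DataFrame(
        {
            "group": [e.group for e in estimates],
            "setting": [e.setting.value for e in estimates],
            "couple_index": [e.couple_index for e in estimates],
            "n": [e.n for e in estimates],
            "k": [e.k for e in estimates],
            "alpha": [e.alpha for e in estimates],
            "beta": [e.beta_param for e in estimates],
            "mean": [e.mean for e in estimates],
            "sd": [e.sd for e in estimates],
        }
    )
    est_frame.to_csv(out / "estimates.csv", index=False)

    totals = cumulative_times(retained)
    rt = response_time_test(
        totals.loc[totals["group"] == "timed", "total_time_s"],
        totals.loc[totals["group"] == "control", "total_time_s"],
    )

    comparisons = {}
    for setting in sorted({e.setting for e in estimates}, key=lambda s: s.value):
        per_group = {}
        normality = []
        for group in ("timed", "control"):
            sub = [e for e in estimates if e.group == group and e.setting == setting]
            per_group[group] = aggregate(sub)
            normality.extend(check_normality(e, rng=est_rng) for e in sub)
        comp = compare_groups(per_group["timed"], per_group["control"], tuple(normality))
        comparisons[setting.value] = {
            "p_timed": comp.estimate_timed.p_s,
            "sd_timed": comp.estimate_timed.sd_s,
            "p_control": comp.estimate_control.p_s,
            "sd_control": comp.estimate_control.sd_s,
            "m_couples": comp.estimate_timed.m_couples,
            "z": comp.z,
            "p_one_sided": comp.p_one_sided,
            "min_shapiro_p": min(n.shapiro_p for n in comp.normality),
        }

    ranking = standardized_ranking(
        retained, couples, seeds["coinflips"], config.starting_capital
    )
    ranking.to_csv(out / "ranking.csv", index=False)

    report = {
        "qc": {
            "n_initial": qc_report.n_initial,
            "n_retained": qc_report.n_retained,
            "frac_correct_all": qc_report.frac_correct_all,
            "frac_correct_retained": qc_report.frac_correct_retained,
        },
        "response_time": dataclasses.asdict(rt),
        "comparisons": comparisons,
    }
    with open(out / "comparison_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)

    if make_figures:
        from .report import plot_estimates, plot_times

        plot_estimates(estimates, comparisons, out / "estimates.png")
        plot_times(totals, out / "times.png")

    artifacts = {
        p.name: _digest(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=_config_snapshot(config),
        seeds=seeds,
        artifacts=artifacts,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest
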