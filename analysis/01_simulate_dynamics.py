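"""Simulate additive and multiplicative wealth trajectories (200 individuals,
500 rounds, start capital 1000) and contrast ensemble-average with
time-average growth — the ergodicity-breaking demonstration that motivates
the experiment. Writes per-round summary curves to results/ and trajectory
figures to scratch/figures/."""

import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ergochoice.dynamics import Bet, Dynamic, ensemble_ev, simulate_trajectories, time_avg_growth

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"

BETS = {
    Dynamic.ADDITIVE: Bet(-100, 150),
    Dynamic.MULTIPLICATIVE: Bet(0.6, 1.5),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
    rows = []
    for dynamic, bet in BETS.items():
        ev = ensemble_ev(bet, dynamic)
        growth = time_avg_growth(bet, dynamic)
        ens = simulate_trajectories(bet, dynamic, 200, 500, 1000.0, seed=2026)
        inc = ens.growth_increments().ravel()
        print(f"[{dynamic.value}] bet {bet.outcome_lo}/{bet.outcome_hi}:")
        print(f"  ensemble average per round : {ev:.4f}")
        print(f"  time-average growth        : {growth:+.4f}")
        print(f"  simulated mean increment   : {inc.mean():+.4f} "
              f"(SE {inc.std(ddof=1) / math.sqrt(inc.size):.4f})")
        print(f"  final ensemble mean capital: {ens.ensemble_mean()[-1]:.3g}, "
              f"median: {ens.ensemble_median()[-1]:.3g}")
        for t in range(0, 501, 10):
            rows.append(
                {
                    "dynamic": dynamic.value,
                    "round": t,
                    "ensemble_mean": ens.ensemble_mean()[t],
                    "ensemble_median": ens.ensemble_median()[t],
                }
            )
        from ergochoice.report import plot_trajectories

        plot_trajectories(ens, FIGURES / f"trajectories_{dynamic.value}.png")
    pd.DataFrame(rows).to_csv(RESULTS / "dynamics_summary.csv", index=False)
    print(
        "\nFinding: in the additive dynamic mean and median capital move "
        "together (ergodic); in the multiplicative dynamic the ensemble mean "
        "grows like 1.05^t while the typical (median) trajectory decays at "
        "rate ln(0.9)/2 — ergodicity is broken."
    )


if __name__ == "__main__":
    main()
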