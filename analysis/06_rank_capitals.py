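"""Rank retained respondents by standardized final capital (shared coin
flips, standardized bet order, start capital 1000). Writes
results/ranking.csv and reports the timed group's median rank."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ergochoice.inference import standardized_ranking
from ergochoice.io import read_bet_table, read_responses

ROOT = Path(__file__).resolve().parent.parent
SEED = 2026


def main() -> None:
    resp_path = ROOT / "scratch" / "responses_retained.csv"
    bets_path = ROOT / "results" / "bet_table.csv"
    if not resp_path.exists() or not bets_path.exists():
        raise SystemExit("run 02_generate_bets.py and 04_quality_filter.py first")
    ranking = standardized_ranking(
        read_responses(resp_path), read_bet_table(bets_path), coinflip_seed=SEED
    )
    ranking.to_csv(ROOT / "results" / "ranking.csv", index=False)
    med = ranking.groupby("group")["rank"].median()
    print(ranking.head(6).to_string(index=False))
    print(f"\nmedian rank out of {len(ranking)}: {med.to_dict()}")
    print("(one shared random run; with so few trials the ranking itself "
          "carries little evidence either way)")


if __name__ == "__main__":
    main()
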