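"""Synthesize the respondent-choice table: 100 respondents, timed group
modelled as noisy time-average optimizers, control group as expected-value-
indifferent choosers. Writes scratch/responses.csv (large) and prints the
group composition."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ergochoice.agents import ExperimentConfig, generate_dataset
from ergochoice.io import read_bet_table, write_responses

ROOT = Path(__file__).resolve().parent.parent
SEED = 2026


def main() -> None:
    bet_path = ROOT / "results" / "bet_table.csv"
    if not bet_path.exists():
        raise SystemExit("run 02_generate_bets.py first")
    couples = read_bet_table(bet_path)
    config = ExperimentConfig(seed=SEED)
    frame = generate_dataset(config, couples)
    out = ROOT / "scratch" / "responses.csv"
    out.parent.mkdir(exist_ok=True)
    write_responses(frame, out)
    sizes = frame.drop_duplicates("respondent_id")["group"].value_counts()
    print(f"wrote {len(frame)} rows ({config.n_respondents} respondents x 80 couples) to {out}")
    print(f"group sizes: {sizes.to_dict()}")


if __name__ == "__main__":
    main()
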