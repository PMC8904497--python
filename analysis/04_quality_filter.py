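"""Apply the no-brainer attention filter (>= 3/5 correct per setting) and
summarize response times. Writes results/qc_respondents.csv,
results/qc_summary.json and scratch/responses_retained.csv."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ergochoice.io import read_responses, write_responses
from ergochoice.qc import apply_filter, summarize_times

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    resp_path = ROOT / "scratch" / "responses.csv"
    if not resp_path.exists():
        raise SystemExit("run 03_synthesize_responses.py first")
    frame = read_responses(resp_path)
    retained, report = apply_filter(frame)
    write_responses(retained, ROOT / "scratch" / "responses_retained.csv")
    report.per_respondent.to_csv(ROOT / "results" / "qc_respondents.csv", index=False)
    times = summarize_times(retained)
    summary = {
        "n_initial": report.n_initial,
        "n_retained": report.n_retained,
        "frac_correct_all": report.frac_correct_all,
        "frac_correct_retained": report.frac_correct_retained,
        "time_summary": times.to_dict(orient="records"),
    }
    (ROOT / "results" / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"retained {report.n_retained}/{report.n_initial} respondents "
          f"({100 * report.frac_correct_all:.1f}% of no-brainer answers correct)")
    print(times.to_string(index=False))


if __name__ == "__main__":
    main()
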