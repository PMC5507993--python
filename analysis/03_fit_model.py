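#!/usr/bin/env python
"""Screen the network cases and fit the two-block logistic model.

Reads results/cases.csv, removes zero-pass successful networks and |z| >
3.29 outliers, reports collinearity (Belsley) and linearity-of-the-logit
(Box-Tidwell) diagnostics, rescales the metrics to 0..10, and fits the
hierarchical model: block 1 = total passes, block 2 = + density, clustering,
centralization.  Writes results/model_report.json and a Table-1-style text
render to results/model_report.txt.
"""

from pathlib import Path

import pandas as pd

from passnet.regression_suite import model_report, render_report, report_to_json, run_analysis

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "cases.csv"
    if not path.exists():
        raise SystemExit("no cases.csv; run analysis/02_build_cases.py first")
    cases = pd.read_csv(path)

    screen, fits, frame = run_analysis(cases)
    rep = model_report(screen, fits)
    report_to_json(rep, RESULTS / "model_report.json")
    text = render_report(rep)
    (RESULTS / "model_report.txt").write_text(text)

    dropped = len(cases) - len(frame)
    print(f"{len(cases)} cases read; {len(screen.zero_pass_ids)} zero-pass successful "
          f"networks and {len(screen.outlier_ids)} outliers removed -> n = {len(frame)}")
    ci = screen.condition_indexes
    print(f"collinearity: max condition index {max(ci):.1f} "
          f"({'flagged' if screen.collinearity_flags else 'no dimension flagged'})")
    worst = min(screen.logit_linearity_p.values())
    print(f"linearity of the logit: smallest interaction p = {worst:.3f} "
          f"({'met' if screen.logit_linear else 'violated'})")
    print()
    print(text)
    print(f"wrote {RESULTS / 'model_report.json'} and .txt")


if __name__ == "__main__":
    main()
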