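"""Primary analysis: univariate screen of all 406 ratio variables.

For each of the four comparisons, every pairwise dCt variable is tested
with the exact Mann–Whitney test (Bonferroni family 4 x 406) and scored by
LOOCV balanced logistic regression.  Writes one filtered table per
comparison (significant variables plus all :nf3 variables) under results/.
"""

from pathlib import Path

from ctratio import COMPARISONS, CtMatrix, MarkerPanel, filter_report_rows, univariate_screen
from ctratio.report import results_table


def main() -> None:
    panel = MarkerPanel()
    results = Path("results")
    matrix = CtMatrix.read_csv(results / "cohort.csv", panel)
    for name, comp in COMPARISONS.items():
        screened = univariate_screen(matrix, comp, panel)
        n_sig = sum(bool(r.significant) for r in screened)
        rows = filter_report_rows(screened)
        table = results_table(rows)
        out = results / f"screen_{name}.csv"
        table.to_csv(out, index=False)
        top = screened[0]
        print(f"{name}: {n_sig}/406 significant after x1624; "
              f"top {top.covariates[0]} "
              f"(p_adj={top.p_adjusted:.2e}, "
              f"cv_acc={top.performance.accuracy:.3f}, "
              f"auc={top.performance.auc:.3f}) -> {out}")


if __name__ == "__main__":
    main()
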