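"""Secondary analysis: exhaustive multi-variable model search.

The full space holds (406*405/2) + (406*405*404/6) = 11,153,835 two- and
three-covariate models per comparison; this desk-scale driver searches the
top 30 variables from each comparison's univariate screen (4,495 models)
and reports the best models by cross-validation accuracy.  The package
supports the full run via sharding (see README).
"""

from pathlib import Path

from ctratio import (COMPARISONS, CtMatrix, MarkerPanel, RatioVariable,
                     count_models, exhaustive_search, univariate_screen)
from ctratio.report import search_table

SUBSET_SIZE = 30
TOP_N = 10


def main() -> None:
    panel = MarkerPanel()
    results = Path("results")
    matrix = CtMatrix.read_csv(results / "cohort.csv", panel)
    print(f"full model space per comparison: "
          f"{count_models(406, (2, 3)):,} subsets of sizes (2, 3)")
    for name, comp in COMPARISONS.items():
        screened = univariate_screen(matrix, comp, panel)
        subset = [RatioVariable.from_name(r.covariates[0])
                  for r in screened[:SUBSET_SIZE]]
        report = exhaustive_search(matrix, comp, panel, sizes=(2, 3),
                                   top_n=TOP_N, variable_subset=subset,
                                   log_every=0)
        out = results / f"search_{name}.csv"
        search_table(report).to_csv(out, index=False)
        best = report.top_models[0]
        perf = best.performance
        print(f"{name}: {report.total_models_evaluated:,} models; best "
              f"{' + '.join(best.covariates)} | acc={perf.accuracy:.3f} "
              f"sens={perf.sensitivity:.3f} spec={perf.specificity:.3f} "
              f"auc={perf.auc:.3f} ({perf.auc_ci_low:.3f}, "
              f"{perf.auc_ci_high:.3f}) -> {out}")


if __name__ == "__main__":
    main()
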