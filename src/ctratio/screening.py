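"""Univariate variable screening and exhaustive 2-/3-covariate model search.

Primary analysis: each of the 406 ratio variables is tested between the two
sides of a binary comparison with the exact Mann–Whitney test, Bonferroni
adjusted over the fixed 4 x 406 family, and scored by leave-one-out
cross-validated balanced logistic regression (accuracy / sensitivity /
specificity at threshold 0.5, DeLong AUC interval).

Secondary analysis: every 2- and 3-variable subset of the 406 variables is
fitted the same way — (406*405/2) + (406*405*404/6) = 11,153,835 models per
comparison — with a streaming top-n ranked by cross-validation accuracy,
then AUC, then covariate names.  The subset space can be sharded
deterministically for parallel execution; serial and merged sharded runs
produce identical reports because pruning never drops a model that could
still tie the running n-th boundary on (accuracy, AUC).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .exact_stats import RankTestResult, exact_mann_whitney, is_significant
from .logistic import loocv_predict
from .panel import CtMatrix, MarkerPanel, RatioVariable, enumerate_variables, evaluate_variables
from .performance import PerformanceReport, evaluate_predictions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSpec:
    """One binary contrast; ``positive_groups`` define the cases whose
    detection rate is reported as sensitivity."""

    name: str
    positive_groups: frozenset[str]
    negative_groups: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive_groups or not self.negative_groups:
            raise ConfigError("comparison sides must be non-empty")
        if self.positive_groups & self.negative_groups:
            raise ConfigError("comparison sides must be disjoint")

    def labels(self, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """(mask of samples in the comparison, binary y with 1 = positive)."""
        pos = groups.isin(self.positive_groups).to_numpy()
        neg = groups.isin(self.negative_groups).to_numpy()
        mask = pos | neg
        return mask, pos[mask].astype(float)


#: The four study contrasts.  Sensitivity orientation follows the report
#: tables: the named group is the positive class (for ALL_vs_AML, ALL).
COMPARISONS: dict[str, ComparisonSpec] = {
    "NTP_vs_others": ComparisonSpec("NTP_vs_others",
                                    frozenset({"NTP"}), frozenset({"ALL", "AML"})),
    "ALL_vs_others": ComparisonSpec("ALL_vs_others",
                                    frozenset({"ALL"}), frozenset({"NTP", "AML"})),
    "AML_vs_others": ComparisonSpec("AML_vs_others",
                                    frozenset({"AML"}), frozenset({"NTP", "ALL"})),
    "ALL_vs_AML": ComparisonSpec("ALL_vs_AML",
                                 frozenset({"ALL"}), frozenset({"AML"})),
}


@dataclass(frozen=True)
class ModelResult:
    """One fitted model (1-3 covariates) with its screening statistics."""

    covariates: tuple[str, ...]
    comparison: str
    performance: PerformanceReport
    p_raw: float | None = None
    p_adjusted: float | None = None
    significant: bool | None = None
    mw_method: str | None = None

    @property
    def key(self) -> tuple:
        """Deterministic ranking key: accuracy desc, AUC desc, names asc."""
        return (-self.performance.accuracy, -self.performance.auc,
                self.covariates)


@dataclass
class SearchReport:
    """Result of an exhaustive model search (possibly one shard of it)."""

    total_models_evaluated: int
    top_models: list[ModelResult]
    top_n: int
    sizes: tuple[int, ...]
    n_shards: int = 1
    shard_index: int = 0
    ranking_key: str = "(cv_accuracy desc, cv_auc desc, covariates asc); boundary ties kept"


def count_models(n_variables: int, sizes: Iterable[int]) -> int:
    """Closed-form size of the model space: sum of C(V, k) over k in sizes."""
    return sum(math.comb(n_variables, k) for k in sorted(set(sizes)))


def iter_subsets(n_variables: int, sizes: Iterable[int],
                 n_shards: int = 1, shard_index: int = 0
                 ) -> Iterator[tuple[int, ...]]:
    """Deterministic enumeration of covariate index subsets.

    Subsets are emitted by ascending size, each size in lexicographic
    index order; shard s takes every n_shards-th subset starting at its
    offset, so the union over shards is an exact partition.
    """
    if n_shards < 1 or not (0 <= shard_index < n_shards):
        raise ConfigError("need 0 <= shard_index < n_shards")
    counter = 0
    for k in sorted(set(sizes)):
        if k < 1 or k > n_variables:
            raise ConfigError(f"subset size {k} out of range")
        for combo in itertools.combinations(range(n_variables), k):
            if counter % n_shards == shard_index:
                yield combo
            counter += 1


def _comparison_data(matrix: CtMatrix, comparison: ComparisonSpec,
                     panel: MarkerPanel,
                     variables: Sequence[RatioVariable],
                     nf3_mode: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    mask, y = comparison.labels(matrix.groups)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValidationError(
            f"comparison {comparison.name} needs >= 2 samples per side")
    sub = matrix.subset(mask)
    values = evaluate_variables(sub, variables, panel, nf3_mode=nf3_mode)
    return values.to_numpy(float), y, list(values.columns)


def univariate_screen(matrix: CtMatrix, comparison: ComparisonSpec,
                      panel: MarkerPanel,
                      variables: Sequence[RatioVariable] | None = None,
                      nf3_mode: str = "geometric_ct",
                      n_variables_family: int = 406,
                      n_comparisons_family: int = 4,
                      alpha: float = 0.05) -> list[ModelResult]:
    """Screen every ratio variable on one comparison.

    Returns one ModelResult per variable, ordered by adjusted p ascending
    (ties by name).  The Bonferroni multiplier defaults to the fixed
    4 x 406 family regardless of how many variables are actually evaluated.
    """
    if variables is None:
        variables = enumerate_variables(panel)
    X, y, names = _comparison_data(matrix, comparison, panel, variables, nf3_mode)
    results = []
    for j, name in enumerate(names):
        col = X[:, j]
        test = exact_mann_whitney(col[y == 1], col[y == 0])
        test = test.adjusted(n_variables_family, n_comparisons_family)
        probs = loocv_predict(col[:, None], y)
        perf = evaluate_predictions(probs, y)
        results.append(ModelResult(
            covariates=(name,), comparison=comparison.name,
            performance=perf, p_raw=test.p_raw, p_adjusted=test.p_adjusted,
            significant=is_significant(test.p_raw, alpha,
                                       n_variables_family, n_comparisons_family),
            mw_method=test.method))
    results.sort(key=lambda r: (r.p_adjusted, r.covariates))
    return results


def filter_report_rows(results: Sequence[ModelResult],
                       nf3_name: str = "nf3") -> list[ModelResult]:
    """The report-table inclusion rule: Bonferroni-significant variables
    plus every variable normalised to nf3."""
    return [r for r in results
            if r.significant
            or any(nf3_name in c.split(":") for c in r.covariates)]


class _TopModels:
    """Streaming top-n keeper that retains (accuracy, AUC) boundary ties.

    Pruning removes only models strictly worse on (accuracy, AUC) than the
    current n-th best, so no model that could appear in the final report
    (which keeps ties with the n-th boundary) is ever discarded — this is
    what makes sharded and serial searches merge to identical reports.
    """

    def __init__(self, top_n: int):
        if top_n < 1:
            raise ConfigError("top_n must be >= 1")
        self.top_n = top_n
        self._items: list[ModelResult] = []

    def push(self, model: ModelResult) -> None:
        self._items.append(model)
        if len(self._items) >= 4 * self.top_n:
            self._prune()

    def _prune(self) -> None:
        self._items.sort(key=lambda m: m.key)
        if len(self._items) <= self.top_n:
            return
        bound = self._items[self.top_n - 1]
        bacc, bauc = bound.performance.accuracy, bound.performance.auc
        self._items = [m for m in self._items
                       if (m.performance.accuracy, m.performance.auc)
                       >= (bacc, bauc)]

    def finalize(self) -> list[ModelResult]:
        self._prune()
        self._items.sort(key=lambda m: m.key)
        return list(self._items)


def exhaustive_search(matrix: CtMatrix, comparison: ComparisonSpec,
                      panel: MarkerPanel,
                      sizes: Iterable[int] = (2, 3),
                      top_n: int = 20,
                      variable_subset: Sequence[RatioVariable] | None = None,
                      nf3_mode: str = "geometric_ct",
                      n_shards: int = 1, shard_index: int = 0,
                      max_models: int | None = None,
                      log_every: int = 100_000) -> SearchReport:
    """Evaluate every covariate subset of the requested sizes by LOOCV.

    Each variable's value vector is computed once and reused across all
    subsets containing it.  ``n_shards``/``shard_index`` restrict the run
    to a deterministic slice of the subset space; ``max_models`` caps the
    number of models actually fitted (for desk-scale runs).
    """
    sizes = tuple(sorted(set(sizes)))
    variables = variable_subset if variable_subset is not None \
        else enumerate_variables(panel)
    if not variables:
        raise ConfigError("empty variable set")
    X, y, names = _comparison_data(matrix, comparison, panel, variables, nf3_mode)
    top = _TopModels(top_n)
    evaluated = 0
    for combo in iter_subsets(len(names), sizes, n_shards, shard_index):
        if max_models is not None and evaluated >= max_models:
            break
        probs = loocv_predict(X[:, combo], y)
        perf = evaluate_predictions(probs, y)
        covs = tuple(sorted(names[j] for j in combo))
        top.push(ModelResult(covariates=covs, comparison=comparison.name,
                             performance=perf))
        evaluated += 1
        if log_every and evaluated % log_every == 0:
            best = top.finalize()[0]
            logger.info("%s: %d models; best so far %s acc=%.3f",
                        comparison.name, evaluated,
                        " + ".join(best.covariates),
                        best.performance.accuracy)
    return SearchReport(total_models_evaluated=evaluated,
                        top_models=top.finalize(), top_n=top_n, sizes=sizes,
                        n_shards=n_shards, shard_index=shard_index)


def merge_search_reports(reports: Sequence[SearchReport]) -> SearchReport:
    """Combine shard reports into the report a serial run would produce."""
    if not reports:
        raise ConfigError("nothing to merge")
    top_n = reports[0].top_n
    sizes = reports[0].sizes
    if any(r.top_n != top_n or r.sizes != sizes for r in reports):
        raise ConfigError("shard reports disagree on top_n or sizes")
    top = _TopModels(top_n)
    for rep in reports:
        for model in rep.top_models:
            top.push(model)
    return SearchReport(
        total_models_evaluated=sum(r.total_models_evaluated for r in reports),
        top_models=top.finalize(), top_n=top_n, sizes=sizes)


#: Display floor for p-values from the CV-prediction separation check.
P_DISPLAY_FLOOR = 2.2e-16


def cv_prediction_test(probs, y) -> RankTestResult:
    """Exact Mann–Whitney test of the out-of-fold probabilities by class.

    Quantifies how strongly cross-validated predictions separate the two
    groups; the raw p is retained exactly, and formatting floors the
    displayed value at 2.2e-16.
    """
    probs = np.asarray(probs, float).ravel()
    y = np.asarray(y).ravel()
    return exact_mann_whitney(probs[y == 1], probs[y == 0])
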