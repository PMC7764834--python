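"""Table formatting and serialization of screening / search results.

Number display follows the report-table conventions: Bonferroni-adjusted
p-values as plain decimals with two significant figures, rendered ">1"
when the uncapped product exceeds 1; metrics to three decimals; AUC as
"0.949 (0.910, 0.989)"; p-values from the CV-separation check floored at
2.2e-16 for display (raw values are retained everywhere internally).
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from typing import Sequence

import pandas as pd

from .screening import ModelResult, P_DISPLAY_FLOOR, SearchReport

try:  # single source of truth for the version string
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("ctratio")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


def format_p_adjusted(p: float | None) -> str:
    """Two-significant-figure plain decimal; ``>1`` above unity."""
    if p is None:
        return ""
    if p > 1.0:
        return ">1"
    if p <= 0.0:
        raise ValueError("adjusted p must be positive")
    exponent = math.floor(math.log10(p))
    decimals = max(0, 1 - exponent)
    return f"{p:.{decimals}f}"


def format_p_floored(p: float, floor: float = P_DISPLAY_FLOOR) -> str:
    """Reporting-limit convention for extremely small p-values."""
    if p < floor:
        return f"<{floor:.1e}".replace("e-", " x 10^-")
    return f"{p:.2g}"


def format_auc_ci(auc: float, lo: float, hi: float) -> str:
    return f"{auc:.3f} ({lo:.3f}, {hi:.3f})"


def results_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Flat table mirroring the report columns."""
    rows = []
    for r in results:
        perf = r.performance
        rows.append({
            "covariates": " + ".join(r.covariates),
            "p_adj_display": format_p_adjusted(r.p_adjusted),
            "p_adjusted": r.p_adjusted,
            "cv_accuracy": round(perf.accuracy, 3),
            "cv_sensitivity": round(perf.sensitivity, 3),
            "cv_specificity": round(perf.specificity, 3),
            "cv_auc": round(perf.auc, 3),
            "auc_ci_low": round(perf.auc_ci_low, 3),
            "auc_ci_high": round(perf.auc_ci_high, 3),
            "auc_display": format_auc_ci(perf.auc, perf.auc_ci_low,
                                         perf.auc_ci_high),
        })
    return pd.DataFrame(rows)


def search_table(report: SearchReport) -> pd.DataFrame:
    table = results_table(report.top_models)
    return table.drop(columns=["p_adj_display", "p_adjusted"])


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int | None) -> None:
    """Sidecar JSON recording what produced an output file."""
    payload = {
        "package": "ctratio",
        "version": _VERSION,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
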