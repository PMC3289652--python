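"""Locked-cutoff validation on the independent test cohort.

Rules trained on the training split are applied *unchanged* to the test
split: :func:`apply_rule` takes no labels, so re-optimization on test data
is impossible by construction.  Per rule the module reports the confusion
counts, sensitivity / specificity / PPV / NPV, exact (Clopper-Pearson) 95%
binomial intervals for sensitivity and specificity, and a Welch t-test on
the test-set ΔCt values, then flags rules passing an inclusive test gate
(default: sensitivity and specificity both ≥ 75%).

Undefined ratios (no positive or no negative predictions) are reported as
missing (NaN), never coerced to 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffpairs import DiffPairMatrix
from .screen import DiffPairRule, welch_t_test, _pct

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMetrics:
    """Confusion counts and derived diagnostic metrics with exact CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    ppv: float
    npv: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    p_value: float = float("nan")


def apply_rule(rule: DiffPairRule, dp: DiffPairMatrix) -> np.ndarray:
    """Predicted labels (True = cancer) for every sample; no labels consumed."""
    # dp.column returns ΔCt in the rule's own orientation, whichever
    # orientation the matrix stores
    return rule.classify(dp.column(rule.pair))


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid successes/trials: k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def confusion_metrics(
    pred: np.ndarray, truth: np.ndarray, level: float = 0.95
) -> ConfusionMetrics:
    """Confusion counts and sens/spec/PPV/NPV with exact binomial CIs.

    ``pred`` and ``truth`` are boolean vectors (True = cancer).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        ppv = float("nan")
        logger.warning("no positive predictions; PPV undefined")
    if tn + fn > 0:
        npv = tn / (tn + fn)
    else:
        npv = float("nan")
        logger.warning("no negative predictions; NPV undefined")
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, sens=sens, spec=spec, ppv=ppv, npv=npv,
        sens_ci=clopper_pearson_ci(tp, tp + fn, level),
        spec_ci=clopper_pearson_ci(tn, tn + fp, level),
    )


def validate_candidates(
    rules: list[DiffPairRule],
    dp_test: DiffPairMatrix,
    meta: pd.DataFrame,
    sens_min: float = 0.75,
    spec_min: float = 0.75,
) -> pd.DataFrame:
    """Evaluate locked rules on the test split and rank the results.

    One row per rule, ranked by descending sens + spec then ascending test
    Welch p-value; ``passed_gate`` flags rules with sensitivity and
    specificity both at or above the (inclusive) gate.
    """
    if not rules:
        raise ValueError("empty rule list")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    test_ids = [s for s in dp_test.sample_ids if meta.loc[s, "split"] == "test"]
    if not test_ids:
        raise ValueError("no test samples in the diffpair matrix")
    dpt = dp_test.subset_samples(test_ids)
    truth = np.array([meta.loc[s, "group"] == "cancer" for s in test_ids])
    if truth.all() or not truth.any():
        raise ValueError("test split must contain both cancers and controls")

    rows = []
    for i, rule in enumerate(rules):
        pred = apply_rule(rule, dpt)
        col = dpt.column(rule.pair)
        _, _, p = welch_t_test(col[truth], col[~truth])
        cm = confusion_metrics(pred, truth)
        cm.p_value = p
        passed = cm.sens >= sens_min and cm.spec >= spec_min
        rows.append({
            "diffpair": rule.name,
            "mirna_a": rule.pair[0], "mirna_b": rule.pair[1],
            "cutoff": rule.cutoff, "direction": rule.direction,
            "PPV": _pct(cm.ppv), "NPV": _pct(cm.npv),
            "SENS": _pct(cm.sens), "SPEC": _pct(cm.spec),
            "ppv_raw": cm.ppv, "npv_raw": cm.npv,
            "sens_raw": cm.sens, "spec_raw": cm.spec,
            "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            "p_value": cm.p_value,
            "sens_ci_lo": cm.sens_ci[0], "sens_ci_hi": cm.sens_ci[1],
            "spec_ci_lo": cm.spec_ci[0], "spec_ci_hi": cm.spec_ci[1],
            "passed_gate": passed,
            "_order": i,
        })
    table = pd.DataFrame(rows)
    table["_score"] = table["sens_raw"] + table["spec_raw"]
    table = (table.sort_values(["_score", "p_value", "_order"],
                               ascending=[False, True, True])
             .drop(columns=["_score", "_order"])
             .reset_index(drop=True))
    return table


def roc_points(rule_pair: tuple[str, str], dp: DiffPairMatrix,
               meta: pd.DataFrame, direction: str = "cancer_above",
               split: str = "test") -> pd.DataFrame:
    """ROC point list (fpr, tpr, threshold) for one diffpair, for plotting."""
    from sklearn.metrics import roc_curve

    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    ids = [s for s in dp.sample_ids if meta.loc[s, "split"] == split]
    dps = dp.subset_samples(ids)
    truth = np.array([meta.loc[s, "group"] == "cancer" for s in ids])
    col = dps.column(rule_pair)
    score = col if direction == "cancer_above" else -col
    fpr, tpr, thr = roc_curve(truth, score)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
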