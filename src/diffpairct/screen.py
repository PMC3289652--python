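"""Training-set screening of diffpairs.

For every ΔCt diffpair column the screen computes, on the training split only:

* a Welch (unequal-variance) two-sample t-test between cancers and controls,
* the ROC AUC via the Mann-Whitney identity, reported ≥ 0.5 with the
  orientation absorbed into the rule direction,
* the cutoff maximizing sensitivity + specificity over both classification
  directions, with the threshold grid at midpoints between adjacent distinct
  sorted values plus ±infinity sentinels,
* the resulting training confusion metrics and the ≥ sens_min / ≥ spec_min
  candidate gate (default 80% / 80%).

P-values are reported raw (no multiplicity correction) and the candidate
gate consults sensitivity and specificity only — never the p-value.  An
optional Benjamini-Hochberg column can be added on request, off by default.

Cutoff ties are broken by (1) larger min(sens, spec), (2) smaller absolute
cutoff, (3) the cancer-above direction; all comparisons on counts so the
tie-breaks are exact.  A sample exactly at the cutoff classifies as control;
with midpoint cutoffs no training sample sits on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffpairs import DiffPairMatrix

CANCER_ABOVE = "cancer_above"
CANCER_BELOW = "cancer_below"


@dataclass(frozen=True)
class DiffPairRule:
    """A locked single-diffpair classifier: one pair, one cutoff, one direction.

    classify(x) = cancer iff (cancer_above and x > cutoff) or
    (cancer_below and x < cutoff); x == cutoff classifies as control.
    """

    pair: tuple[str, str]
    cutoff: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (CANCER_ABOVE, CANCER_BELOW):
            raise ValueError(f"bad direction {self.direction!r}")

    def classify(self, delta_ct: np.ndarray) -> np.ndarray:
        """Boolean predictions (True = cancer) for a vector of ΔCt values."""
        x = np.asarray(delta_ct, dtype=float)
        if self.direction == CANCER_ABOVE:
            return x > self.cutoff
        return x < self.cutoff

    def flipped(self) -> "DiffPairRule":
        """The identical classifier expressed in the reversed pair orientation."""
        other = CANCER_BELOW if self.direction == CANCER_ABOVE else CANCER_ABOVE
        return DiffPairRule((self.pair[1], self.pair[0]), -self.cutoff, other)

    @property
    def name(self) -> str:
        return f"Diff({self.pair[0]},{self.pair[1]})"


@dataclass
class ScreenRecord:
    """Per-diffpair training statistics; one row of the candidate table."""

    rule: DiffPairRule
    t_stat: float
    df: float
    p_value: float
    auc: float
    sens: float
    spec: float
    ppv: float          # nan when no positive predictions
    npv: float          # nan when no negative predictions
    is_candidate: bool


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided unequal-variance t-test; returns (t, Welch-Satterthwaite df, p).

    The sign of t follows mean(x) − mean(y).  With both variances zero and
    equal means the test is uninformative and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def roc_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, str]:
    """ROC AUC of a ΔCt column via the Mann-Whitney identity.

    ``labels`` is boolean (True = cancer).  Returns (auc, orientation) with
    auc ≥ 0.5; orientation is the rule direction achieving it.
    """
    auc_above = _auc_above(np.asarray(values, float)[:, None],
                           np.asarray(labels, bool))[0]
    if auc_above >= 0.5:
        return float(auc_above), CANCER_ABOVE
    return float(1.0 - auc_above), CANCER_BELOW


def _auc_above(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise P(cancer > control) + 0.5 P(tie) for a (n, p) matrix."""
    n_ca = int(y.sum())
    n_co = int((~y).sum())
    if n_ca == 0 or n_co == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values, axis=0, method="average")
    rank_sum = ranks[y].sum(axis=0)
    return (rank_sum - n_ca * (n_ca + 1) / 2) / (n_ca * n_co)


def _cutoff_scan(values: np.ndarray, y: np.ndarray):
    """Vectorized exhaustive cutoff search over all columns of ``values``.

    Evaluates both directions at every midpoint between adjacent distinct
    sorted values plus ±inf sentinels; maximizes sens + spec with exact
    count-based tie-breaking.

    Returns arrays (cutoff, direction_above, tp, fp, tn, fn), one entry per
    column, for the chosen rule.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    n, p = values.shape
    n_ca = int(y.sum())
    n_co = n - n_ca
    if n_ca == 0 or n_co == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(values, axis=0, kind="stable")
    v_sorted = np.take_along_axis(values, order, axis=0)
    y_sorted = y[order]                                    # (n, p)

    # cum_ca[k] = cancers among the k smallest values
    cum_ca = np.zeros((n + 1, p), dtype=np.int64)
    np.cumsum(y_sorted, axis=0, out=cum_ca[1:])
    k = np.arange(n + 1)[:, None]
    cum_co = k - cum_ca

    # cutoff k sits between sorted positions k-1 and k
    cut = np.empty((n + 1, p))
    cut[0] = -np.inf
    cut[n] = np.inf
    if n > 1:
        cut[1:n] = (v_sorted[:-1] + v_sorted[1:]) / 2.0
    valid = np.ones((n + 1, p), dtype=bool)
    if n > 1:
        valid[1:n] = v_sorted[:-1] < v_sorted[1:]

    # direction cancer_above: predict cancer for the n-k largest values
    tp_a = n_ca - cum_ca
    tn_a = cum_co
    # direction cancer_below: predict cancer for the k smallest values
    tp_b = cum_ca
    tn_b = n_co - cum_co

    def stack(arr_a, arr_b):
        return np.concatenate([arr_a, arr_b], axis=0)      # (2(n+1), p)

    tp = stack(tp_a, tp_b)
    tn = stack(tn_a, tn_b)
    cut2 = stack(cut, cut)
    valid2 = stack(valid, valid)
    dir_above = np.zeros((2 * (n + 1), 1), dtype=bool)
    dir_above[: n + 1] = True
    dir_above = np.broadcast_to(dir_above, tp.shape)

    # exact integer objective: sens + spec ∝ tp*n_co + tn*n_ca
    score = tp * n_co + tn * n_ca
    min_score = np.minimum(tp * n_co, tn * n_ca)           # min(sens, spec)
    NEG = -1
    score = np.where(valid2, score, NEG)

    best = score.max(axis=0)
    m = score == best
    ms = np.where(m, min_score, NEG)
    m &= ms == ms.max(axis=0)
    ac = np.where(m, np.abs(cut2), np.inf)
    m &= ac == ac.min(axis=0)
    dpref = np.where(m & dir_above, 2, np.where(m, 1, 0))
    idx = dpref.argmax(axis=0)

    cols = np.arange(p)
    return (
        cut2[idx, cols],
        dir_above[idx, cols],
        tp[idx, cols],
        n_ca - tp[idx, cols],          # fn
        tn[idx, cols],
        n_co - tn[idx, cols],          # fp
    )


def select_cutoff(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, str, float, float]:
    """Cutoff and direction maximizing sensitivity + specificity.

    Returns (cutoff, direction, sens, spec) with training (resubstitution)
    sensitivity and specificity at the chosen rule.
    """
    y = np.asarray(labels, dtype=bool)
    cut, above, tp, fn, tn, fp = _cutoff_scan(
        np.asarray(values, float)[:, None], y
    )
    sens = tp[0] / (tp[0] + fn[0])
    spec = tn[0] / (tn[0] + fp[0])
    return (float(cut[0]), CANCER_ABOVE if above[0] else CANCER_BELOW,
            float(sens), float(spec))


def _welch_columns(values: np.ndarray, y: np.ndarray):
    """Columnwise Welch t, df, two-sided p for cancer vs control."""
    x1 = values[y]
    x2 = values[~y]
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 training samples")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    # degenerate columns (zero variance in both groups)
    zero = se2 == 0
    equal = zero & (m1 == m2)
    t = np.where(equal, 0.0, t)
    df = np.where(zero, n1 + n2 - 2, df)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(equal, 1.0, p)
    return t, df, p


def screen_all(
    dp: DiffPairMatrix,
    meta: pd.DataFrame,
    sens_min: float = 0.80,
    spec_min: float = 0.80,
) -> list[ScreenRecord]:
    """Screen every diffpair on the training split.

    Returns one :class:`ScreenRecord` per pair, ordered by descending
    sens + spec, then ascending p-value, then pair enumeration order.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    train_ids = [s for s in dp.sample_ids if meta.loc[s, "split"] == "train"]
    if not train_ids:
        raise ValueError("no training samples in the diffpair matrix")
    dpt = dp.subset_samples(train_ids)
    y = np.array([meta.loc[s, "group"] == "cancer" for s in train_ids])
    if y.all() or not y.any():
        raise ValueError("training split must contain both cancers and controls")

    t, df, p = _welch_columns(dpt.delta_ct, y)
    auc_above = _auc_above(dpt.delta_ct, y)
    auc = np.maximum(auc_above, 1.0 - auc_above)
    cut, above, tp, fn, tn, fp = _cutoff_scan(dpt.delta_ct, y)

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    with np.errstate(invalid="ignore"):
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        npv = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
    gate = (sens >= sens_min) & (spec >= spec_min)

    records = [
        ScreenRecord(
            rule=DiffPairRule(dp.pairs[k], float(cut[k]),
                              CANCER_ABOVE if above[k] else CANCER_BELOW),
            t_stat=float(t[k]), df=float(df[k]), p_value=float(p[k]),
            auc=float(auc[k]), sens=float(sens[k]), spec=float(spec[k]),
            ppv=float(ppv[k]), npv=float(npv[k]), is_candidate=bool(gate[k]),
        )
        for k in range(dp.n_pairs)
    ]
    pair_pos = {pair: k for k, pair in enumerate(dp.pairs)}
    records.sort(key=lambda r: (-(r.sens + r.spec), r.p_value,
                                pair_pos[r.rule.pair]))
    return records


def unique_mirnas(records: list[ScreenRecord]) -> list[str]:
    """Sorted deduplicated union of pair members across records."""
    names: set[str] = set()
    for r in records:
        names.update(r.rule.pair)
    return sorted(names)


def screen_table(records: list[ScreenRecord], add_bh: bool = False) -> pd.DataFrame:
    """Candidate table with integer-percentage display columns.

    ``add_bh=True`` appends Benjamini-Hochberg adjusted p-values as an extra
    column; gating never uses p-values of either kind.
    """
    rows = {
        "diffpair": [r.rule.name for r in records],
        "mirna_a": [r.rule.pair[0] for r in records],
        "mirna_b": [r.rule.pair[1] for r in records],
        "cutoff": [r.rule.cutoff for r in records],
        "direction": [r.rule.direction for r in records],
        "PPV": [_pct(r.ppv) for r in records],
        "NPV": [_pct(r.npv) for r in records],
        "SENS": [_pct(r.sens) for r in records],
        "SPEC": [_pct(r.spec) for r in records],
        "ppv_raw": [r.ppv for r in records],
        "npv_raw": [r.npv for r in records],
        "sens_raw": [r.sens for r in records],
        "spec_raw": [r.spec for r in records],
        "t_stat": [r.t_stat for r in records],
        "df": [r.df for r in records],
        "p_value": [r.p_value for r in records],
        "AUC": [r.auc for r in records],
        "is_candidate": [r.is_candidate for r in records],
    }
    table = pd.DataFrame(rows)
    if add_bh:
        from statsmodels.stats.multitest import multipletests

        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def rules_from_table(table: pd.DataFrame) -> list[DiffPairRule]:
    """Reconstruct locked rules from a written candidate table."""
    required = {"mirna_a", "mirna_b", "cutoff", "direction"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"rules table missing columns: {sorted(missing)}")
    return [
        DiffPairRule((str(r.mirna_a), str(r.mirna_b)), float(r.cutoff),
                     str(r.direction))
        for r in table.itertuples()
    ]


def _pct(x: float) -> float:
    """Display percentage, rounded half away from zero; nan passes through."""
    if np.isnan(x):
        return np.nan
    return float(np.floor(100.0 * x + 0.5))
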