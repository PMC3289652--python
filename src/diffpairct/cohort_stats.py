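"""Two-sided Fisher exact tests on 2×2 demographic tables.

Checks cohort balance (cancer status vs smoking history, sex, ...) the way
case-control biomarker studies report it.  The two-sided p-value is the sum
of hypergeometric point probabilities, over all tables with the observed
margins, that do not exceed the observed table's own probability — the
convention most software (and the study design this package reproduces)
uses; doubling one tail gives different numbers and is not implemented.

Point probabilities are accumulated on the log scale (log-factorials via
``scipy.special.gammaln``), so the sum is exact to well below 1e-12 relative
error for any desk-scale table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

# tolerance for "probability not exceeding the observed" on the log scale;
# guards against log-scale round-off deciding inclusion of equal-probability tables
_REL_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = cohort group, columns = attribute yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError(f"counts must be non-negative integers: {counts}")
        if sum(counts) == 0:
            raise ValueError("table is all zero")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for the hypergeometric with margins r1, r2 and c1."""
    n = r1 + r2
    return float(
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(r2 + 1) - gammaln(c1 - a + 1) - gammaln(r2 - (c1 - a) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table.

    Degenerate margins (an all-zero row or column) make the table
    deterministic under the null; p = 1 by convention.
    """
    r1, r2, c1, c2 = t.margins
    if 0 in (r1, r2, c1, c2):
        logger.info("degenerate margins %s; p = 1 by convention", t.margins)
        return 1.0
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    log_obs = _log_hypergeom_pmf(t.a, r1, r2, c1)
    threshold = log_obs + _REL_EPS
    support = np.arange(a_min, a_max + 1)
    log_p = np.array([_log_hypergeom_pmf(int(a), r1, r2, c1) for a in support])
    included = log_p <= threshold
    # log-sum-exp of the included probabilities
    sel = log_p[included]
    m = sel.max()
    p = float(math.exp(m) * np.exp(sel - m).sum())
    return min(p, 1.0)


def counts_from_percent(pct: float, n: int) -> tuple[int, float]:
    """Reconstruct a count from a printed percentage of a known group size.

    Rounds half away from zero and returns (count, back-computed percentage);
    logs a consistency warning when the back-computed percentage differs
    from the printed one by more than 0.5.
    """
    if not (0 <= pct <= 100):
        raise ValueError(f"percentage out of range: {pct}")
    if n < 1:
        raise ValueError(f"group size must be >= 1: {n}")
    count = int(math.floor(pct * n / 100.0 + 0.5))
    back = 100.0 * count / n
    if abs(back - pct) > 0.5:
        logger.warning("percentage %s%% of n=%d -> count %d (%.1f%%): "
                       "printed value inconsistent with an integer count",
                       pct, n, count, back)
    return count, back


def attribute_association(meta, attribute: str) -> tuple[ContingencyTable2x2, float]:
    """2×2 table and Fisher p for cancer status vs a binary metadata attribute."""
    sub = meta[["group", attribute]].dropna()
    pos = sub[attribute].astype(bool)
    cancer = sub["group"] == "cancer"
    t = ContingencyTable2x2(
        a=int((cancer & pos).sum()), b=int((cancer & ~pos).sum()),
        c=int((~cancer & pos).sum()), d=int((~cancer & ~pos).sum()),
    )
    return t, fisher_exact_two_sided(t)
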