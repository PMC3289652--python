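"""Pairwise ΔCt ("diffpair") construction.

For every unordered pair of miRNAs (a, b) the diffpair value in a sample is
ΔCt = Ct(a) − Ct(b), a within-sample log2 abundance ratio.  Because any
per-sample additive offset (serum input, extraction yield, RT efficiency)
cancels in the subtraction, diffpairs need no external normalizer — the
property the screening design relies on.

Orientation convention: pairs are emitted once, ordered by source column
index (first member precedes the second in the input column order), and
ΔCt is Ct(first) − Ct(second).  Pair enumeration is lexicographic over
column index pairs, so the layout is reproducible from the input file alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr_io import CtMatrix


@dataclass
class DiffPairMatrix:
    """Samples × miRNA-pairs matrix of ΔCt values.

    ``delta_ct`` has shape (n_samples, n_pairs) with
    ``delta_ct[s, k] = Ct(pairs[k][0]) − Ct(pairs[k][1])`` for sample s.
    ``any_censored[s, k]`` is True when either member of the pair was
    censored at the cycle limit in that sample.
    """

    sample_ids: list[str]
    pairs: list[tuple[str, str]]
    delta_ct: np.ndarray
    any_censored: np.ndarray

    def __post_init__(self) -> None:
        self.delta_ct = np.asarray(self.delta_ct, dtype=float)
        self.any_censored = np.asarray(self.any_censored, dtype=bool)
        if self.delta_ct.shape != (len(self.sample_ids), len(self.pairs)):
            raise ValueError("delta_ct shape does not match sample/pair counts")
        if self.any_censored.shape != self.delta_ct.shape:
            raise ValueError("any_censored shape mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_index(self, pair: tuple[str, str]) -> int:
        """Index of a pair, accepting either orientation (flipped → same pair)."""
        try:
            return self.pairs.index(pair)
        except ValueError:
            pass
        flipped = (pair[1], pair[0])
        try:
            return self.pairs.index(flipped)
        except ValueError:
            raise KeyError(f"pair {pair} not present") from None

    def column(self, pair: tuple[str, str]) -> np.ndarray:
        """ΔCt column for a pair; flipped orientation returns the negated column."""
        k = self.pair_index(pair)
        col = self.delta_ct[:, k]
        return col if self.pairs[k] == tuple(pair) else -col

    def subset_samples(self, sample_ids: list[str]) -> "DiffPairMatrix":
        pos = [self.sample_ids.index(s) for s in sample_ids]
        return DiffPairMatrix(
            list(sample_ids), self.pairs,
            self.delta_ct[pos], self.any_censored[pos],
        )

    def to_wide_frame(self) -> pd.DataFrame:
        cols = [f"{a}|{b}" for a, b in self.pairs]
        return pd.DataFrame(self.delta_ct, index=self.sample_ids, columns=cols)

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.delta_ct.shape
        return pd.DataFrame({
            "sample_id": np.repeat(self.sample_ids, p),
            "mirna_a": [a for a, _ in self.pairs] * n,
            "mirna_b": [b for _, b in self.pairs] * n,
            "delta_ct": self.delta_ct.ravel(),
            "any_censored": self.any_censored.ravel(),
        })


def enumerate_pairs(mirna_ids: list[str]) -> list[tuple[str, str]]:
    """All C(m, 2) unordered pairs, canonical orientation = input column order."""
    ids = list(mirna_ids)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 miRNAs, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA names")
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def compute_diffpairs(m: CtMatrix) -> DiffPairMatrix:
    """ΔCt matrix over all unordered miRNA pairs of a Ct matrix."""
    pairs = enumerate_pairs(m.mirna_ids)
    ct = m.ct.to_numpy()
    cen = m.censored.to_numpy()
    nm = m.n_mirnas
    ii, jj = np.triu_indices(nm, k=1)      # lexicographic (i, j), i < j
    delta = ct[:, ii] - ct[:, jj]
    any_cen = cen[:, ii] | cen[:, jj]
    return DiffPairMatrix(m.sample_ids, pairs, delta, any_cen)
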